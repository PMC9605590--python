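"""OH-stretch deconvolution into water-mobility states.

The high-wavenumber region (2600-3800 cm^-1) of a collagenous tissue is
modelled as a sum of ten Gaussian lines: four lipid/protein CH-stretch
lines (2850, 2880, 2940, 2980 cm^-1), two NH lines (3060, 3330 cm^-1) and
four OH lines describing water sub-populations classified by hydrogen-bond
strength — tightly bound (DAA-OH, 3005 cm^-1), strongly bound (DDAA-OH,
3277 cm^-1), weakly bound (DA-OH, 3458 cm^-1) and free water (3604 cm^-1,
one line standing for the very-weakly-bound plus unbound sum).

Each water state is quantified by the area under its Gaussian normalised
to the area of the 2940 cm^-1 protein line; total water content is the
sum of the four normalised states.  Centers may move at most +/- 5 cm^-1
from nominal and widths at most +/- 20 cm^-1, following common practice
for OH-stretch decompositions.  "Width" means the Gaussian sigma
throughout (FWHM = 2*sqrt(2*ln 2) * sigma ~ 2.355 sigma).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .exceptions import (
    CoverageError,
    NormalizationError,
    ParameterError,
)
from .spectra import RamanSpectrum, Region

__all__ = [
    "subtract_hwn_baseline",
    "ComponentRole",
    "GaussianComponent",
    "DeconvolutionResult",
    "WaterStateProfile",
    "NOMINAL_CENTERS",
    "NOMINAL_SIGMAS",
    "WATER_ROLES",
    "deconvolve_hwn",
    "component_auc",
    "water_profile",
    "water_kinetics",
    "WaterKinetics",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


class ComponentRole(enum.Enum):
    LIPID_PROTEIN_2850 = "lipid_protein_2850"
    LIPID_PROTEIN_2880 = "lipid_protein_2880"
    PROTEIN_2940 = "protein_2940"
    LIPID_PROTEIN_2980 = "lipid_protein_2980"
    WATER_TIGHT_3005 = "water_tight_3005"
    NH_3060 = "nh_3060"
    WATER_STRONG_3277 = "water_strong_3277"
    NH_3330 = "nh_3330"
    WATER_WEAK_3458 = "water_weak_3458"
    WATER_FREE_3604 = "water_free_3604"


#: Nominal line centers, cm^-1 (fit bound: +/- 5 cm^-1).
NOMINAL_CENTERS: dict[ComponentRole, float] = {
    ComponentRole.LIPID_PROTEIN_2850: 2850.0,
    ComponentRole.LIPID_PROTEIN_2880: 2880.0,
    ComponentRole.PROTEIN_2940: 2940.0,
    ComponentRole.LIPID_PROTEIN_2980: 2980.0,
    ComponentRole.WATER_TIGHT_3005: 3005.0,
    ComponentRole.NH_3060: 3060.0,
    ComponentRole.WATER_STRONG_3277: 3277.0,
    ComponentRole.NH_3330: 3330.0,
    ComponentRole.WATER_WEAK_3458: 3458.0,
    ComponentRole.WATER_FREE_3604: 3604.0,
}

#: Nominal sigmas, cm^-1 (fit bound: +/- 20 cm^-1, floor 2 cm^-1).
NOMINAL_SIGMAS: dict[ComponentRole, float] = {
    ComponentRole.LIPID_PROTEIN_2850: 20.0,
    ComponentRole.LIPID_PROTEIN_2880: 20.0,
    ComponentRole.PROTEIN_2940: 20.0,
    ComponentRole.LIPID_PROTEIN_2980: 20.0,
    ComponentRole.WATER_TIGHT_3005: 30.0,
    ComponentRole.NH_3060: 40.0,
    ComponentRole.WATER_STRONG_3277: 80.0,
    ComponentRole.NH_3330: 40.0,
    ComponentRole.WATER_WEAK_3458: 80.0,
    ComponentRole.WATER_FREE_3604: 40.0,
}

#: Water states in report order, keyed by short state name.
WATER_ROLES: dict[str, ComponentRole] = {
    "tight": ComponentRole.WATER_TIGHT_3005,
    "strong": ComponentRole.WATER_STRONG_3277,
    "weak": ComponentRole.WATER_WEAK_3458,
    "free": ComponentRole.WATER_FREE_3604,
}

CENTER_TOL = 5.0
SIGMA_TOL = 20.0
SIGMA_FLOOR = 2.0
#: Prior standard deviations for the shape penalty (cm^-1); see
#: :func:`deconvolve_hwn`.
CENTER_PRIOR_SD = 2.0
SIGMA_PRIOR_SD = 5.0


#: Windows essentially free of CH/NH/OH signal, used to anchor the
#: high-wavenumber baseline.
HWN_BASELINE_WINDOWS: tuple[tuple[float, float], ...] = ((2600.0, 2700.0), (3750.0, 3800.0))


def subtract_hwn_baseline(s: RamanSpectrum, poly_order: int = 2) -> RamanSpectrum:
    """Subtract a polynomial fitted to the signal-free edges of an HWN spectrum.

    The OH-stretch envelope occupies most of the high-wavenumber axis,
    so a lower-envelope baseline would swallow the broad water bands.
    Instead the baseline polynomial is fitted only inside
    :data:`HWN_BASELINE_WINDOWS`, where CH/NH/OH lines contribute
    negligibly.
    """
    if s.region is not Region.HWN:
        raise CoverageError("subtract_hwn_baseline expects an HWN-region spectrum")
    wn, y = s.wavenumbers, s.intensities
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in HWN_BASELINE_WINDOWS:
        mask |= (wn >= lo) & (wn <= hi)
    if mask.sum() < poly_order + 2:
        raise CoverageError("too few edge points to anchor the HWN baseline")
    fit = np.polynomial.Polynomial.fit(wn[mask], y[mask], poly_order)
    return s.with_intensities(y - fit(wn))


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted Gaussian line: amplitude * exp(-(w-center)^2 / (2 sigma^2))."""

    role: ComponentRole
    center_cm1: float
    sigma_cm1: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma_cm1 <= 0:
            raise ParameterError("sigma_cm1 must be > 0")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")

    @property
    def auc(self) -> float:
        """Closed-form area: amplitude * sigma * sqrt(2*pi)."""
        return self.amplitude * self.sigma_cm1 * SQRT_2PI

    @property
    def fwhm_cm1(self) -> float:
        return 2.0 * math.sqrt(2.0 * math.log(2.0)) * self.sigma_cm1

    def evaluate(self, wn: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((np.asarray(wn, dtype=float) - self.center_cm1) ** 2)
            / (2.0 * self.sigma_cm1**2)
        )


def component_auc(g: GaussianComponent) -> float:
    """Area under one Gaussian line (closed form)."""
    return g.auc


@dataclass(frozen=True)
class DeconvolutionResult:
    """Ten fitted components (sorted by center) with fit diagnostics."""

    components: tuple[GaussianComponent, ...]
    rss: float
    converged: bool

    def by_role(self) -> dict[ComponentRole, GaussianComponent]:
        return {c.role: c for c in self.components}

    def model(self, wn: np.ndarray) -> np.ndarray:
        return np.sum([c.evaluate(wn) for c in self.components], axis=0)


def _sum_gaussians(wn: np.ndarray, params: np.ndarray) -> np.ndarray:
    amp = params[0::3]
    cen = params[1::3]
    sig = params[2::3]
    return np.sum(
        amp[:, None] * np.exp(-((wn[None, :] - cen[:, None]) ** 2) / (2 * sig[:, None] ** 2)),
        axis=0,
    )


def deconvolve_hwn(
    s: RamanSpectrum,
    centers: Mapping[ComponentRole, float] | None = None,
    sigmas: Mapping[ComponentRole, float] | None = None,
) -> DeconvolutionResult:
    """Bounded least-squares fit of ten Gaussian lines to an HWN spectrum.

    The spectrum must be baseline-subtracted and cover at least
    [2700, 3700] cm^-1.  Amplitudes are bounded >= 0, centers within
    +/- 5 cm^-1 of nominal and sigmas within +/- 20 cm^-1 of nominal.

    Ten heavily overlapping Gaussians with free shapes are nearly
    degenerate — neighbouring lines can trade area with almost no change
    in the residual — so the fit is a maximum-a-posteriori estimate:
    centers and sigmas carry Gaussian priors at their nominal values
    (sd 2 and 5 cm^-1), weighted by the per-point noise level estimated
    from second differences of the spectrum.  The penalty therefore
    vanishes for noise-free data (recovery is exact) and merely
    stabilises the decomposition when noise would otherwise let area
    wander between neighbours.

    Initialisation is deterministic — amplitudes from a non-negative
    linear solve with shapes fixed at nominal — so the decomposition is
    reproducible bit-for-bit.  Non-convergence returns the best attempt
    flagged ``converged=False`` rather than raising.
    """
    if s.region is not Region.HWN:
        raise CoverageError("deconvolve_hwn expects an HWN-region spectrum")
    if s.wavenumbers[0] > 2700.0 or s.wavenumbers[-1] < 3700.0:
        raise CoverageError(
            f"spectrum spans [{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}] cm^-1; "
            "deconvolution requires coverage of [2700, 3700]"
        )
    centers = dict(NOMINAL_CENTERS if centers is None else centers)
    sigmas = dict(NOMINAL_SIGMAS if sigmas is None else sigmas)
    roles = list(NOMINAL_CENTERS)

    wn = s.wavenumbers
    y = s.intensities
    y_scale = max(float(np.max(np.abs(y))), 1e-12)
    # per-point noise from second differences (signal is smooth on this grid);
    # floored at 0.1% of the signal scale so the shape prior still guards
    # against small systematic residuals (e.g. imperfect baselines) when the
    # random noise is negligible
    noise_sd = max(
        float(np.std(np.diff(y, n=2)) / math.sqrt(6.0)), 1e-3 * y_scale
    )

    basis = np.column_stack(
        [
            np.exp(-((wn - centers[r]) ** 2) / (2.0 * sigmas[r] ** 2))
            for r in roles
        ]
    )
    amp0, _ = nnls(basis, y)

    x0, lb, ub = [], [], []
    c_nom, s_nom = [], []
    for i, role in enumerate(roles):
        c0, s0 = centers[role], sigmas[role]
        c_nom.append(c0)
        s_nom.append(s0)
        x0 += [max(float(amp0[i]), 1e-6 * y_scale), c0, s0]
        lb += [0.0, c0 - CENTER_TOL, max(s0 - SIGMA_TOL, SIGMA_FLOOR)]
        ub += [np.inf, c0 + CENTER_TOL, s0 + SIGMA_TOL]
    c_nom = np.array(c_nom)
    s_nom = np.array(s_nom)

    def residuals(p: np.ndarray) -> np.ndarray:
        data = _sum_gaussians(wn, p) - y
        pen_c = noise_sd * (p[1::3] - c_nom) / CENTER_PRIOR_SD
        pen_s = noise_sd * (p[2::3] - s_nom) / SIGMA_PRIOR_SD
        return np.concatenate([data, pen_c, pen_s])

    res = least_squares(
        residuals,
        x0=np.array(x0),
        bounds=(np.array(lb), np.array(ub)),
        method="trf",
        x_scale=np.array([y_scale, 10.0, 10.0] * len(roles)),
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=20000,
    )
    comps = []
    for i, role in enumerate(roles):
        amp, cen, sig = res.x[3 * i : 3 * i + 3]
        comps.append(GaussianComponent(role, float(cen), float(sig), max(float(amp), 0.0)))
    comps.sort(key=lambda c: c.center_cm1)
    data_resid = _sum_gaussians(wn, res.x) - y
    return DeconvolutionResult(
        components=tuple(comps),
        rss=float(np.sum(data_resid**2)),
        converged=bool(res.success),
    )


@dataclass(frozen=True)
class WaterStateProfile:
    """Normalised water-state areas at one depth and time.

    Each state ratio is its Gaussian area divided by the 2940 cm^-1
    protein area; ``total_water`` is the sum of the four state ratios
    (exact identity by construction).
    """

    depth_um: float
    time_s: float | None
    auc: dict[ComponentRole, float]
    tight: float
    strong: float
    weak: float
    free: float
    total_water: float

    def ratio(self, state: str) -> float:
        return getattr(self, state)


def water_profile(
    components: Sequence[GaussianComponent] | DeconvolutionResult,
    depth_um: float,
    time_s: float | None,
) -> WaterStateProfile:
    """Normalise water-state areas to the protein 2940 cm^-1 area."""
    if isinstance(components, DeconvolutionResult):
        components = components.components
    by_role = {c.role: c for c in components}
    missing = set(NOMINAL_CENTERS) - set(by_role)
    if missing:
        raise ParameterError(f"missing components: {sorted(r.value for r in missing)}")
    aucs = {role: by_role[role].auc for role in NOMINAL_CENTERS}
    protein = aucs[ComponentRole.PROTEIN_2940]
    # a fit can return a numerically-zero protein amplitude rather than 0.0
    if protein <= 0 or protein < 1e-9 * max(aucs.values()):
        raise NormalizationError("protein 2940 cm^-1 area is zero; ratios undefined")
    ratios = {name: aucs[role] / protein for name, role in WATER_ROLES.items()}
    return WaterStateProfile(
        depth_um=depth_um,
        time_s=time_s,
        auc=aucs,
        tight=ratios["tight"],
        strong=ratios["strong"],
        weak=ratios["weak"],
        free=ratios["free"],
        total_water=ratios["tight"] + ratios["strong"] + ratios["weak"] + ratios["free"],
    )


@dataclass(frozen=True)
class WaterKinetics:
    """Long-format water-state kinetics plus a before/after summary."""

    table: pd.DataFrame  # depth_um, time_s, state, ratio
    summary: pd.DataFrame  # state rows x (depth, before, after) columns
    insufficient: bool  # True when any depth had < 2 time points


def water_kinetics(
    profiles: Sequence[WaterStateProfile],
    after_time_s: float = 90.0,
) -> WaterKinetics:
    """Tabulate water-state ratios over time and summarise before/after.

    "Before" is the untreated profile (``time_s=None``) when present,
    else the earliest time point; "after" is the profile closest to
    ``after_time_s``.  Total water is included as a fifth state row.
    """
    states = list(WATER_ROLES) + ["total_water"]
    rows = []
    for p in profiles:
        for st in states:
            rows.append(
                {
                    "depth_um": p.depth_um,
                    "time_s": p.time_s,
                    "state": st,
                    "ratio": p.total_water if st == "total_water" else p.ratio(st),
                }
            )
    table = pd.DataFrame(rows)

    summary_rows = []
    insufficient = False
    for depth in sorted({p.depth_um for p in profiles}):
        at_depth = [p for p in profiles if p.depth_um == depth]
        timed = sorted(
            (p for p in at_depth if p.time_s is not None), key=lambda p: p.time_s
        )
        untreated = [p for p in at_depth if p.time_s is None]
        if len(timed) + len(untreated) < 2:
            insufficient = True
        before = untreated[0] if untreated else (timed[0] if timed else None)
        after = (
            min(timed, key=lambda p: abs(p.time_s - after_time_s)) if timed else None
        )
        if before is None or after is None:
            insufficient = True
            continue
        for st in states:
            summary_rows.append(
                {
                    "depth_um": depth,
                    "state": st,
                    "before": before.total_water if st == "total_water" else before.ratio(st),
                    "after": after.total_water if st == "total_water" else after.ratio(st),
                }
            )
    return WaterKinetics(table, pd.DataFrame(summary_rows), insufficient)
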