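"""Fick's-second-law erfc model and nonlinear (D, C0) fitting.

One-dimensional diffusion of an agent into a semi-infinite medium whose
surface is held at the saturation concentration C0 has the closed-form
solution

    C(x, t) = C0 * erfc( x / (2 * sqrt(D * t)) )

with D the diffusion coefficient (cm^2/s), x the depth (cm) and t the
time since application (s).  This module evaluates the profile, verifies
it against an explicit finite-difference solution of the underlying PDE,
fits (D, C0) to depth-resolved concentration time series by bounded
multi-start least squares, and averages the per-band fits into a
per-depth summary.

Depths are handled in micrometres at the API surface and converted to cm
internally (1 um = 1e-4 cm); D is reported in cm^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc

from .exceptions import CompletenessError, ParameterError, StabilityError
from .kinetics import BandTimeSeries, SeriesKind

__all__ = [
    "concentration_profile",
    "fd_oracle",
    "fit_diffusion",
    "summarize_depth",
    "DiffusionFitResult",
    "DepthSummary",
    "round_sig",
    "REFERENCE_BAND_CENTERS",
    "table1_style",
]

#: Collagen reference band centers a per-depth summary must contain.
REFERENCE_BAND_CENTERS: tuple[float, ...] = (938.0, 1003.0, 1247.0, 1270.0, 1665.0)

#: Fit bounds for D (cm^2/s) and C0 (%).
D_BOUNDS = (1e-8, 1e-3)
C0_BOUNDS = (0.0, 60.0)
#: Multi-start grid for D; C0 starts at the series maximum.
D_STARTS = (1e-6, 1e-5, 1e-4)


def concentration_profile(C0: float, D: float, x_cm, t_s):
    """Semi-infinite erfc concentration profile C0*erfc(x/(2*sqrt(D*t))).

    At ``t = 0`` and ``x > 0`` the profile is 0 (initial condition); at
    ``x = 0`` it is C0 (constant-surface boundary).  ``x_cm`` and
    ``t_s`` may be scalars or broadcastable arrays.
    """
    if D <= 0:
        raise ParameterError(f"D must be > 0, got {D}")
    if C0 < 0:
        raise ParameterError(f"C0 must be >= 0, got {C0}")
    x = np.asarray(x_cm, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if np.any(x < 0) or np.any(t < 0):
        raise ParameterError("x and t must be >= 0")
    x, t = np.broadcast_arrays(x, t)
    out = np.zeros(x.shape)
    pos = t > 0
    with np.errstate(divide="ignore"):
        out[pos] = C0 * erfc(x[pos] / (2.0 * np.sqrt(D * t[pos])))
    out[x == 0] = C0
    return float(out) if out.ndim == 0 else out


def fd_oracle(
    C0: float,
    D: float,
    x_eval_cm: Sequence[float],
    t_eval_s: Sequence[float],
    *,
    dx_cm: float | None = None,
    dt_s: float | None = None,
    domain_factor: float = 10.0,
    nx: int = 1500,
) -> np.ndarray:
    """Explicit finite-difference solution of the diffusion PDE.

    Solves ``dC/dt = D d2C/dx2`` on ``[0, L]`` with ``C(0, t) = C0``,
    ``C(L, t) = 0`` and ``C(x, 0) = 0``, where the domain depth ``L`` is
    at least ``domain_factor * sqrt(D * t_max)`` so the far boundary
    approximates a semi-infinite medium.  Returns the field sampled at
    the requested evaluation points, shape ``(len(t_eval), len(x_eval))``.

    The forward-time centred-space scheme requires
    ``D * dt / dx^2 <= 0.5``; grids supplied explicitly that violate the
    bound raise :class:`StabilityError`.  Auto-chosen grids use
    ``r = 0.4``.
    """
    if D <= 0:
        raise ParameterError(f"D must be > 0, got {D}")
    x_eval = np.asarray(x_eval_cm, dtype=float)
    t_eval = np.asarray(t_eval_s, dtype=float)
    if np.any(np.diff(t_eval) < 0):
        raise ParameterError("t_eval_s must be non-decreasing")
    t_max = float(t_eval[-1]) if t_eval.size else 0.0

    L = max(
        domain_factor * math.sqrt(D * t_max) if t_max > 0 else 0.0,
        2.0 * float(x_eval.max(initial=0.0)),
        1e-6,
    )
    if dx_cm is None:
        dx_cm = L / nx
    if dt_s is None:
        dt_s = 0.4 * dx_cm**2 / D
    r = D * dt_s / dx_cm**2
    if r > 0.5 + 1e-12:
        raise StabilityError(
            f"explicit scheme unstable: D*dt/dx^2 = {r:.3g} > 0.5"
        )

    x = np.arange(0.0, L + dx_cm / 2, dx_cm)
    u = np.zeros_like(x)
    u[0] = C0  # boundary value held from t = 0+

    out = np.empty((t_eval.size, x_eval.size))
    t_now = 0.0
    for i, target in enumerate(t_eval):
        span = target - t_now
        if span > 1e-15:
            n_steps = max(1, math.ceil(span / dt_s))
            dt_i = span / n_steps  # <= dt_s, still stable
            ri = D * dt_i / dx_cm**2
            for _ in range(n_steps):
                u[1:-1] += ri * (u[2:] - 2.0 * u[1:-1] + u[:-2])
                u[0] = C0
                u[-1] = 0.0
            t_now = target
        if target == 0.0:
            row = np.zeros_like(x)
            row[0] = C0
        else:
            row = u
        out[i] = np.interp(x_eval, x, row)
    return out


@dataclass(frozen=True)
class DiffusionFitResult:
    """Fitted (D, C0) for one reference band at one depth."""

    depth_cm: float
    band_cm1: float
    D: float  # cm^2/s
    C0: float  # %
    sd_D: float
    sd_C0: float
    rss: float
    n_points: int
    converged: bool
    degenerate: bool = False  # all-zero input series
    non_monotone: bool = False  # series declines late; erfc cannot represent it

    @property
    def depth_um(self) -> float:
        return self.depth_cm * 1e4


def _fit_residual(params: np.ndarray, t: np.ndarray, y: np.ndarray, x_cm: float):
    log10_D, C0 = params
    model = concentration_profile(C0, 10.0**log10_D, x_cm, t)
    return model - y


def fit_diffusion(
    series: BandTimeSeries,
    depth_um: float | None = None,
    *,
    d_starts: Sequence[float] = D_STARTS,
) -> DiffusionFitResult:
    """Least-squares fit of the erfc profile to a TRGC concentration series.

    D is optimised on a log10 scale within ``D_BOUNDS`` from each start
    in ``d_starts`` (C0 initialised at the series maximum, bounded by
    ``C0_BOUNDS``); the lowest-residual solution is kept.  Standard
    errors come from the Jacobian at the optimum (delta method for the
    log-D parameterisation).  A series that never rises above zero is
    returned as a degenerate C0 = 0 result rather than an exception, and
    a series that declines after its maximum is flagged non-monotone —
    the erfc model saturates and cannot represent a late decline, so the
    residual captures it instead.
    """
    if series.kind is not SeriesKind.TRGC_CONCENTRATION:
        raise ParameterError(
            f"fit_diffusion expects a trgc_concentration series, got {series.kind.value}"
        )
    if len(series) < 5:
        raise ParameterError(f"need >= 5 time points, got {len(series)}")
    depth = series.depth_um if depth_um is None else depth_um
    x_cm = depth * 1e-4
    t = series.times_s
    y = series.values

    # late-decline flag: maximum well before the end and a real drop after it
    peak = int(np.argmax(y))
    span = float(np.ptp(y)) or 1.0
    non_monotone = bool(
        peak < len(y) - 2 and (y[peak] - y[peak:].min()) > 0.05 * span
    )

    y_max = float(y.max())
    if y_max <= 0:
        return DiffusionFitResult(
            depth_cm=x_cm, band_cm1=series.band.center_cm1, D=D_BOUNDS[0], C0=0.0,
            sd_D=float("nan"), sd_C0=float("nan"), rss=float(np.sum(y**2)),
            n_points=len(series), converged=True, degenerate=True,
            non_monotone=non_monotone,
        )

    c0_init = min(max(y_max, 1e-6), C0_BOUNDS[1])
    lb = [math.log10(D_BOUNDS[0]), C0_BOUNDS[0]]
    ub = [math.log10(D_BOUNDS[1]), C0_BOUNDS[1]]
    best = None
    for d0 in d_starts:
        res = least_squares(
            _fit_residual,
            x0=[math.log10(d0), c0_init],
            bounds=(lb, ub),
            args=(t, y, x_cm),
            method="trf",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
            max_nfev=5000,
        )
        if best is None or res.cost < best.cost:
            best = res

    log10_D, C0 = best.x
    D = 10.0**log10_D
    rss = float(2.0 * best.cost)
    n = len(series)
    dof = max(n - 2, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        sd_log10_D = math.sqrt(max(cov[0, 0], 0.0))
        sd_D = math.log(10.0) * D * sd_log10_D
        sd_C0 = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        sd_D = sd_C0 = float("nan")
    return DiffusionFitResult(
        depth_cm=x_cm, band_cm1=series.band.center_cm1, D=float(D), C0=float(C0),
        sd_D=sd_D, sd_C0=sd_C0, rss=rss, n_points=n,
        converged=bool(best.success), non_monotone=non_monotone,
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class DepthSummary:
    """Per-depth arithmetic means of (D, C0) across the reference bands."""

    depth_um: float
    per_band: dict[float, tuple[float, float]]  # center -> (D, C0)
    mean_D: float
    mean_C0: float


def summarize_depth(
    results: Sequence[DiffusionFitResult] | Mapping[float, tuple[float, float]],
    depth_um: float | None = None,
) -> DepthSummary:
    """Average the five per-band (D, C0) fits of one depth.

    Accepts either fit results or a plain ``{band_center: (D, C0)}``
    mapping (useful for summarising externally tabulated values).  All
    five reference bands must be present exactly once.
    """
    if isinstance(results, Mapping):
        per_band = {float(k): (float(d), float(c)) for k, (d, c) in results.items()}
        if depth_um is None:
            raise ParameterError("depth_um is required with a plain mapping")
        depth = depth_um
    else:
        results = list(results)
        per_band = {r.band_cm1: (r.D, r.C0) for r in results}
        if len(per_band) != len(results):
            raise CompletenessError("duplicate band in depth summary")
        depths = {r.depth_um for r in results}
        if len(depths) != 1:
            raise CompletenessError(f"mixed depths in one summary: {sorted(depths)}")
        depth = depths.pop() if depth_um is None else depth_um
    missing = set(REFERENCE_BAND_CENTERS) - set(per_band)
    extra = set(per_band) - set(REFERENCE_BAND_CENTERS)
    if missing or extra:
        raise CompletenessError(
            f"summary needs exactly bands {REFERENCE_BAND_CENTERS}; "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    ds = [per_band[c][0] for c in REFERENCE_BAND_CENTERS]
    c0s = [per_band[c][1] for c in REFERENCE_BAND_CENTERS]
    return DepthSummary(
        depth_um=depth,
        per_band=per_band,
        mean_D=float(np.mean(ds)),
        mean_C0=float(np.mean(c0s)),
    )


def table1_style(summaries: Sequence[DepthSummary], sig: int = 2) -> pd.DataFrame:
    """Report table: band rows plus an Average row per depth, 2 sig figs."""
    rows = []
    for s in sorted(summaries, key=lambda s: s.depth_um):
        for center in REFERENCE_BAND_CENTERS:
            d, c0 = s.per_band[center]
            rows.append(
                {
                    "depth_um": s.depth_um,
                    "band": f"{center:g} cm-1",
                    "D_cm2_s": round_sig(d, sig),
                    "C0_pct": round_sig(c0, sig),
                }
            )
        rows.append(
            {
                "depth_um": s.depth_um,
                "band": "Average",
                "D_cm2_s": round_sig(s.mean_D, sig),
                "C0_pct": round_sig(s.mean_C0, sig),
            }
        )
    return pd.DataFrame(rows)
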