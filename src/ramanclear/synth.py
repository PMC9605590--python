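"""Synthetic experiment generator.

Emulates the measurement design the analysis pipeline targets: a
glycerol-in-water calibration series (15 standards, 0-50% v/v), a
fingerprint depth/time series driven by a known erfc concentration
profile times a clearing-efficiency gain, and a high-wavenumber series
built from ten Gaussian lines with prescribed water-state trajectories.
Every stage of the pipeline is therefore testable against known
generative parameters without any external data.

Default conditions mirror the experiment being emulated: depths 50, 100,
150 and 200 um; treatment times 0-390 s in 30 s steps; per-depth
diffusion coefficients and saturation concentrations at the reported
per-depth averages; water-state ratios at the reported before/after
values per depth.  The clearing gain follows a saturating exponential
``g(t) = 1 + (g_max - 1)(1 - exp(-t/tau))`` with a markedly weaker gain
at 200 um, where clearing efficiency is several-fold lower.  Noise is
multiplicative Gaussian (shot-noise-like, cv x signal) plus a small
additive floor.  All randomness flows from one seeded generator, so the
same seed and spec give bit-identical spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diffusion import concentration_profile
from .exceptions import ParameterError
from .spectra import (
    COLLAGEN_BANDS,
    GLYCEROL_BANDS,
    RamanSpectrum,
    Region,
)

__all__ = [
    "OCGain",
    "SyntheticExperimentSpec",
    "FPExperiment",
    "HWNExperiment",
    "synth_calibration_series",
    "synth_fp_experiment",
    "synth_hwn_experiment",
    "DEFAULT_TRUE_D",
    "DEFAULT_TRUE_C0",
    "DEFAULT_WATER_RATIOS",
]

#: Per-depth generative diffusion coefficients, cm^2/s.
DEFAULT_TRUE_D: dict[float, float] = {
    50.0: 9.6e-6,
    100.0: 1.2e-5,
    150.0: 2.2e-5,
    200.0: 3.0e-5,
}

#: Per-depth generative saturation concentrations, % v/v.
DEFAULT_TRUE_C0: dict[float, float] = {
    50.0: 20.0,
    100.0: 2.9,
    150.0: 1.6,
    200.0: 0.6,
}

#: Per-depth (before, after) water-state ratios relative to protein.
DEFAULT_WATER_RATIOS: dict[float, dict[str, tuple[float, float]]] = {
    50.0: {"tight": (0.20, 0.12), "strong": (6.00, 4.12),
           "weak": (3.49, 2.18), "free": (0.73, 0.48)},
    100.0: {"tight": (0.13, 0.15), "strong": (4.57, 3.42),
            "weak": (2.47, 1.80), "free": (0.61, 0.36)},
    150.0: {"tight": (0.22, 0.19), "strong": (4.60, 3.58),
            "weak": (2.41, 1.70), "free": (0.82, 0.53)},
    200.0: {"tight": (0.18, 0.177), "strong": (6.53, 4.44),
            "weak": (3.24, 2.15), "free": (1.27, 0.66)},
}

_COLLAGEN_BASE_AMPLITUDES: dict[float, float] = {
    938.0: 60.0, 1003.0: 80.0, 1247.0: 55.0, 1270.0: 50.0, 1665.0: 100.0,
}
#: Relative responses of the glycerol bands (485 cm^-1 = 1).
_GLYCEROL_RELATIVE: dict[float, float] = {
    485.0: 1.0, 849.0: 1.3, 1054.0: 0.9, 1466.0: 0.7,
}

_HWN_FIXED_AMPLITUDES: dict[str, float] = {
    "lp_2850": 60.0, "lp_2880": 70.0, "protein_2940": 100.0,
    "lp_2980": 50.0, "nh_3060": 30.0, "nh_3330": 20.0,
}
_HWN_CENTERS: dict[str, float] = {
    "lp_2850": 2850.0, "lp_2880": 2880.0, "protein_2940": 2940.0,
    "lp_2980": 2980.0, "tight": 3005.0, "nh_3060": 3060.0,
    "strong": 3277.0, "nh_3330": 3330.0, "weak": 3458.0, "free": 3604.0,
}
_HWN_SIGMAS: dict[str, float] = {
    "lp_2850": 20.0, "lp_2880": 20.0, "protein_2940": 20.0, "lp_2980": 20.0,
    "tight": 30.0, "nh_3060": 40.0, "strong": 80.0, "nh_3330": 40.0,
    "weak": 80.0, "free": 40.0,
}


@dataclass(frozen=True)
class OCGain:
    """Saturating clearing gain ``1 + (g_max - 1)(1 - exp(-t/tau))``."""

    g_max: float = 2.0
    tau_s: float = 60.0

    def __post_init__(self) -> None:
        if self.g_max < 1.0:
            raise ParameterError("g_max must be >= 1 for a clearing scenario")
        if self.tau_s <= 0:
            raise ParameterError("tau_s must be > 0")

    def __call__(self, t_s: float) -> float:
        return 1.0 + (self.g_max - 1.0) * (1.0 - math.exp(-float(t_s) / self.tau_s))


def _default_oc_gains() -> dict[float, OCGain]:
    return {
        50.0: OCGain(2.0, 45.0),
        100.0: OCGain(1.9, 60.0),
        150.0: OCGain(1.8, 90.0),
        200.0: OCGain(1.25, 60.0),
    }


@dataclass(frozen=True)
class SyntheticExperimentSpec:
    """Fully parameterised synthetic experiment.

    ``baseline_coeffs`` are polynomial coefficients in the normalised
    axis coordinate u in [0, 1] (constant term first).  ``glycerol_response``
    is the 485 cm^-1 peak amplitude per % glycerol, the generative analogue
    of the calibration slope.
    """

    seed: int = 0
    depths_um: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)
    times_s: tuple[float, ...] = tuple(float(t) for t in range(0, 391, 30))
    true_D: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_D))
    true_C0: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_C0))
    oc_gain: Mapping[float, OCGain] = field(default_factory=_default_oc_gains)
    noise_cv: float = 0.02
    noise_floor: float = 0.3
    baseline_coeffs: tuple[float, ...] = (20.0, 10.0, -5.0)
    glycerol_response: float = 1.5
    collagen_amplitudes: Mapping[float, float] = field(
        default_factory=lambda: dict(_COLLAGEN_BASE_AMPLITUDES)
    )
    band_sigma_cm1: float = 6.0
    fp_step_cm1: float = 1.0
    hwn_step_cm1: float = 2.0
    n_untreated_replicates: int = 4

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.noise_floor < 0:
            raise ParameterError("noise_floor must be >= 0")
        for depth in self.depths_um:
            if depth not in self.true_D or self.true_D[depth] <= 0:
                raise ParameterError(f"true_D missing or <= 0 for depth {depth}")
            if depth not in self.true_C0 or self.true_C0[depth] < 0:
                raise ParameterError(f"true_C0 missing or < 0 for depth {depth}")
            if depth not in self.oc_gain:
                raise ParameterError(f"oc_gain missing for depth {depth}")
        if list(self.times_s) != sorted(set(self.times_s)):
            raise ParameterError("times_s must be strictly increasing")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent seeded stream; all spec randomness flows from here."""
        return np.random.default_rng([int(self.seed) % (2**31), int(stream)])


def _fp_axis(spec: SyntheticExperimentSpec) -> np.ndarray:
    return np.arange(400.0, 1800.0 + spec.fp_step_cm1 / 2, spec.fp_step_cm1)


def _hwn_axis(spec: SyntheticExperimentSpec) -> np.ndarray:
    return np.arange(2600.0, 3800.0 + spec.hwn_step_cm1 / 2, spec.hwn_step_cm1)


def _baseline(wn: np.ndarray, coeffs: Sequence[float]) -> np.ndarray:
    if not coeffs:
        return np.zeros_like(wn)
    u = (wn - wn[0]) / (wn[-1] - wn[0])
    return np.polynomial.polynomial.polyval(u, np.asarray(coeffs, dtype=float))


def _gauss(wn: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-((wn - center) ** 2) / (2.0 * sigma**2))


def _add_noise(
    signal: np.ndarray, spec: SyntheticExperimentSpec, rng: np.random.Generator
) -> np.ndarray:
    out = signal * (1.0 + spec.noise_cv * rng.standard_normal(signal.shape))
    if spec.noise_floor > 0:
        out = out + spec.noise_floor * rng.standard_normal(signal.shape)
    return out


def _fp_signal(
    spec: SyntheticExperimentSpec, gain: float, glycerol_pct: float
) -> np.ndarray:
    wn = _fp_axis(spec)
    y = _baseline(wn, spec.baseline_coeffs)
    for band in COLLAGEN_BANDS:
        amp = spec.collagen_amplitudes[band.center_cm1] * gain
        y = y + _gauss(wn, band.center_cm1, spec.band_sigma_cm1, amp)
    gly_amp = spec.glycerol_response * glycerol_pct * gain
    for band in GLYCEROL_BANDS:
        y = y + _gauss(
            wn, band.center_cm1, spec.band_sigma_cm1,
            gly_amp * _GLYCEROL_RELATIVE[band.center_cm1],
        )
    return y


def synth_calibration_series(
    spec: SyntheticExperimentSpec, n_standards: int = 15
) -> list[tuple[float, RamanSpectrum]]:
    """Glycerol-in-water standards, 0-50% v/v, on the fingerprint grid.

    The 485 cm^-1 amplitude is exactly linear in concentration with
    slope ``spec.glycerol_response`` before noise and baseline.
    """
    if n_standards < 3:
        raise ParameterError(f"need >= 3 standards, got {n_standards}")
    rng = spec.rng(101)
    wn = _fp_axis(spec)
    out = []
    for i, conc in enumerate(np.linspace(0.0, 50.0, n_standards)):
        y = _baseline(wn, spec.baseline_coeffs)
        for band in GLYCEROL_BANDS:
            amp = spec.glycerol_response * conc * _GLYCEROL_RELATIVE[band.center_cm1]
            y = y + _gauss(wn, band.center_cm1, spec.band_sigma_cm1, amp)
        y = _add_noise(y, spec, rng)
        out.append(
            (
                float(conc),
                RamanSpectrum(wn, y, Region.FP, sample_id=f"cal-{i:02d}"),
            )
        )
    return out


@dataclass(frozen=True)
class FPExperiment:
    """Fingerprint depth/time series plus untreated references."""

    spec: SyntheticExperimentSpec
    untreated: dict[float, list[RamanSpectrum]]  # depth -> replicates
    treated: dict[float, list[RamanSpectrum]]  # depth -> time-ordered spectra

    def true_concentration(self, depth_um: float, t_s: float) -> float:
        return concentration_profile(
            self.spec.true_C0[depth_um], self.spec.true_D[depth_um],
            depth_um * 1e-4, t_s,
        )


def synth_fp_experiment(spec: SyntheticExperimentSpec) -> FPExperiment:
    """Simulate the fingerprint clearing experiment.

    At each depth and time, collagen amplitudes are the untreated
    amplitudes times the clearing gain, and the glycerol 485 cm^-1
    amplitude is the calibration response times the erfc concentration
    times the same gain — clearing inflates glycerol and collagen bands
    alike, which is exactly the crosstalk the TRGC correction removes.
    Untreated references have gain 1 and zero glycerol.
    """
    rng = spec.rng(202)
    untreated: dict[float, list[RamanSpectrum]] = {}
    treated: dict[float, list[RamanSpectrum]] = {}
    for depth in spec.depths_um:
        untreated[depth] = []
        for k in range(spec.n_untreated_replicates):
            y = _add_noise(_fp_signal(spec, 1.0, 0.0), spec, rng)
            untreated[depth].append(
                RamanSpectrum(
                    _fp_axis(spec), y, Region.FP, depth_um=depth, time_s=None,
                    sample_id=f"ref-d{depth:g}-r{k}",
                )
            )
        gain_fn = spec.oc_gain[depth]
        series = []
        for t in spec.times_s:
            conc = concentration_profile(
                spec.true_C0[depth], spec.true_D[depth], depth * 1e-4, t
            )
            y = _add_noise(_fp_signal(spec, gain_fn(t), conc), spec, rng)
            series.append(
                RamanSpectrum(
                    _fp_axis(spec), y, Region.FP, depth_um=depth, time_s=float(t),
                    sample_id=f"fp-d{depth:g}-t{t:g}",
                )
            )
        treated[depth] = series
    return FPExperiment(spec, untreated, treated)


@dataclass(frozen=True)
class HWNExperiment:
    """High-wavenumber series with known water-state ratio trajectories."""

    spec: SyntheticExperimentSpec
    untreated: dict[float, list[RamanSpectrum]]
    treated: dict[float, list[RamanSpectrum]]
    ratios: dict[float, dict[str, tuple[float, float]]]  # depth -> state -> (before, after)
    tau_s: float

    def generative_ratio(self, depth_um: float, state: str, t_s: float | None) -> float:
        """Ratio the generator used at this depth/state/time (None = before)."""
        before, after = self.ratios[depth_um][state]
        if t_s is None:
            return before
        return after + (before - after) * math.exp(-float(t_s) / self.tau_s)


def synth_hwn_experiment(
    spec: SyntheticExperimentSpec,
    water_ratios: Mapping[float, Mapping[str, tuple[float, float]]] | None = None,
    tau_s: float = 30.0,
    protein_amplitude: float | None = None,
) -> HWNExperiment:
    """Simulate the high-wavenumber water-state experiment.

    Each spectrum is a sum of the ten Gaussian lines; lipid/protein and
    NH amplitudes are constant while the four water-state amplitudes are
    set so their area ratios to protein follow an exponential approach
    from the "before" to the "after" value with time constant ``tau_s``
    (dehydration kinetics).  ``protein_amplitude=0`` produces spectra
    whose downstream normalisation must fail, for error-path testing.
    """
    if water_ratios is None:
        water_ratios = DEFAULT_WATER_RATIOS
    ratios = {
        float(d): {s: (float(b), float(a)) for s, (b, a) in states.items()}
        for d, states in water_ratios.items()
    }
    rng = spec.rng(303)
    wn = _hwn_axis(spec)
    amp_protein = (
        _HWN_FIXED_AMPLITUDES["protein_2940"]
        if protein_amplitude is None
        else float(protein_amplitude)
    )
    protein_area = amp_protein * _HWN_SIGMAS["protein_2940"]

    def build(depth: float, t: float | None, label: str) -> RamanSpectrum:
        y = _baseline(wn, spec.baseline_coeffs)
        for key, amp in _HWN_FIXED_AMPLITUDES.items():
            use = amp_protein if key == "protein_2940" else amp
            y = y + _gauss(wn, _HWN_CENTERS[key], _HWN_SIGMAS[key], use)
        for state in ("tight", "strong", "weak", "free"):
            before, after = ratios[depth][state]
            r = before if t is None else after + (before - after) * math.exp(-t / tau_s)
            amp = r * protein_area / _HWN_SIGMAS[state]
            y = y + _gauss(wn, _HWN_CENTERS[state], _HWN_SIGMAS[state], amp)
        y = _add_noise(y, spec, rng)
        return RamanSpectrum(
            wn, y, Region.HWN, depth_um=depth, time_s=t, sample_id=label
        )

    untreated: dict[float, list[RamanSpectrum]] = {}
    treated: dict[float, list[RamanSpectrum]] = {}
    for depth in spec.depths_um:
        if depth not in ratios:
            raise ParameterError(f"water_ratios missing depth {depth}")
        untreated[depth] = [
            build(depth, None, f"hwn-ref-d{depth:g}-r{k}")
            for k in range(spec.n_untreated_replicates)
        ]
        treated[depth] = [
            build(depth, float(t), f"hwn-d{depth:g}-t{t:g}") for t in spec.times_s
        ]
    return HWNExperiment(spec, untreated, treated, ratios, float(tau_s))
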