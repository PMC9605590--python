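"""Linear glycerol calibration.

The glycerol marker band at 485 cm^-1 scales linearly with the glycerol
volume fraction in water, so an ordinary least-squares line through
(concentration %, band intensity) pairs maps measured intensities back to
concentrations.  Predictions below zero (noise around zero glycerol) are
clamped to 0% and flagged rather than rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .exceptions import CalibrationError, InversionError
from .spectra import BandDefinition, GLYCEROL_BAND, RamanSpectrum, band_intensity

__all__ = [
    "CalibrationModel",
    "ConcentrationPrediction",
    "fit_calibration",
    "predict_concentration",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted intensity-vs-concentration line.

    ``slope`` is in intensity counts per % glycerol; ``intercept`` in
    counts at 0%.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    band: BandDefinition = GLYCEROL_BAND

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "band": {
                "center_cm1": self.band.center_cm1,
                "half_window_cm1": self.band.half_window_cm1,
                "label": self.band.label,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        band = BandDefinition(**d["band"])
        return cls(d["slope"], d["intercept"], d["r_squared"], d["n_points"], band)

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


class ConcentrationPrediction(NamedTuple):
    concentration_pct: float
    clamped: bool  # True when a negative raw prediction was clamped to 0


def fit_calibration(
    standards: Sequence[tuple[float, RamanSpectrum | float]],
    band: BandDefinition = GLYCEROL_BAND,
) -> CalibrationModel:
    """OLS line through (concentration %, intensity) calibration standards.

    Each standard is ``(concentration_pct, value)`` where the value is
    either a pre-extracted band intensity or a (baseline-corrected)
    spectrum from which the band intensity is taken.
    """
    if len(standards) < 3:
        raise CalibrationError(f"need >= 3 standards, got {len(standards)}")
    conc = np.array([float(c) for c, _ in standards])
    if np.any(conc < 0) or np.any(conc > 100):
        raise CalibrationError("concentrations must lie in [0, 100]%")
    if np.unique(conc).size < 3:
        raise CalibrationError("need >= 3 distinct concentrations")
    vals = np.array(
        [
            band_intensity(v, band).intensity if isinstance(v, RamanSpectrum) else float(v)
            for _, v in standards
        ]
    )
    res = stats.linregress(conc, vals)
    fitted = res.intercept + res.slope * conc
    ss_res = float(np.sum((vals - fitted) ** 2))
    ss_tot = float(np.sum((vals - vals.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        n_points=int(conc.size),
        band=band,
    )


def predict_concentration(
    model: CalibrationModel, intensity: float
) -> ConcentrationPrediction:
    """Invert the calibration line: (I - intercept) / slope.

    Negative predictions are clamped to 0% with ``clamped=True``; there
    is no upper clamp.
    """
    if model.slope == 0:
        raise InversionError("calibration slope is zero; cannot invert")
    raw = (float(intensity) - model.intercept) / model.slope
    if raw < 0:
        return ConcentrationPrediction(0.0, True)
    return ConcentrationPrediction(raw, False)
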