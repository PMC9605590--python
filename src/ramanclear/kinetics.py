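"""Optical-clearing efficiency and the reconstructed glycerol signal.

Clearing of the layers above the probed depth inflates every Raman band
recorded below them.  Collagen is immobile, so the rise of a collagen band
relative to its untreated value measures that inflation: the clearing
efficiency ``OC_eff(t) = I_OC(t) / I_0``.  Dividing the glycerol marker
intensity by ``OC_eff`` removes the crosstalk and leaves the part of the
signal due to glycerol actually present at that depth (the reconstructed
glycerol signal, ``TRGC = I_gly / OC_eff``); the calibration line then
converts it to a volume-fraction concentration.

Because a global instrument rescaling multiplies ``I_gly`` and ``I_OC``
alike, TRGC is invariant under it — the defining property of the
correction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, predict_concentration
from .exceptions import (
    AlignmentError,
    CorrectionError,
    ReferenceIntensityError,
    SpectrumValidationError,
)
from .spectra import (
    BandDefinition,
    COLLAGEN_BANDS,
    GLYCEROL_BAND,
    RamanSpectrum,
    average_replicates,
    band_intensity,
    baseline_subtract,
    smooth_savgol,
)

__all__ = [
    "SeriesKind",
    "BandTimeSeries",
    "oc_efficiency",
    "trgc",
    "oc_efficiency_series",
    "build_trgc_series",
    "band_series_from_spectra",
    "analyze_fp_experiment",
    "TrgcAnalysis",
]


class SeriesKind(enum.Enum):
    RAW = "raw"
    OC_EFF = "oc_eff"
    TRGC_INTENSITY = "trgc_intensity"
    TRGC_CONCENTRATION = "trgc_concentration"


@dataclass(frozen=True)
class BandTimeSeries:
    """Per-band values versus treatment time at one fixed depth."""

    depth_um: float
    band: BandDefinition
    times_s: np.ndarray
    values: np.ndarray
    kind: SeriesKind

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise SpectrumValidationError("times and values lengths differ")
        if t.size and not np.all(np.diff(t) > 0):
            raise SpectrumValidationError("times_s must be strictly increasing")
        if self.kind is SeriesKind.OC_EFF and np.any(v <= 0):
            raise SpectrumValidationError("oc_eff values must be > 0")
        t.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times_s.size)


def oc_efficiency(i_oc, i_0):
    """Clearing efficiency ``I_OC / I_0`` (scalar or array ``i_oc``)."""
    i_0 = float(i_0)
    if i_0 <= 0:
        raise ReferenceIntensityError(f"untreated reference intensity {i_0} <= 0")
    return np.asarray(i_oc, dtype=float) / i_0 if np.ndim(i_oc) else float(i_oc) / i_0


def trgc(i_gly, oc_eff):
    """Clearing-corrected glycerol signal ``I_gly / OC_eff``."""
    arr = np.ndim(i_gly) or np.ndim(oc_eff)
    eff = np.asarray(oc_eff, dtype=float)
    if np.any(eff <= 0):
        raise CorrectionError("oc_eff must be > 0")
    out = np.asarray(i_gly, dtype=float) / eff
    return out if arr else float(out)


def oc_efficiency_series(raw: BandTimeSeries, i_0: float) -> BandTimeSeries:
    """Convert a raw collagen intensity series to a clearing-efficiency series."""
    if raw.kind is not SeriesKind.RAW:
        raise CorrectionError("oc_efficiency_series expects a raw intensity series")
    return BandTimeSeries(
        raw.depth_um, raw.band, raw.times_s, oc_efficiency(raw.values, i_0),
        SeriesKind.OC_EFF,
    )


def _check_alignment(a: BandTimeSeries, b: BandTimeSeries) -> None:
    if a.depth_um != b.depth_um:
        raise AlignmentError("series depths differ")
    if len(a) != len(b) or not np.allclose(a.times_s, b.times_s):
        raise AlignmentError("series time axes differ")


def build_trgc_series(
    glycerol_series: BandTimeSeries,
    collagen_series: Mapping[float, BandTimeSeries],
    untreated_refs: Mapping[float, float],
    calibration: CalibrationModel,
) -> dict[float, BandTimeSeries]:
    """TRGC concentration series, one per collagen reference band.

    Parameters
    ----------
    glycerol_series
        Raw glycerol 485 cm^-1 intensity versus time at one depth.
    collagen_series
        Raw collagen intensity series keyed by band center (cm^-1), on
        the same time axis and depth.
    untreated_refs
        Untreated collagen band intensities ``I_0``, same keys.
    calibration
        Line mapping corrected intensity to concentration (%).
    """
    out: dict[float, BandTimeSeries] = {}
    for center, col in collagen_series.items():
        _check_alignment(glycerol_series, col)
        eff = oc_efficiency(col.values, untreated_refs[center])
        corrected = trgc(glycerol_series.values, eff)
        conc = np.array(
            [predict_concentration(calibration, v).concentration_pct for v in corrected]
        )
        out[center] = BandTimeSeries(
            glycerol_series.depth_um, col.band, glycerol_series.times_s, conc,
            SeriesKind.TRGC_CONCENTRATION,
        )
    return out


def _preprocess(
    s: RamanSpectrum,
    baseline_order: int | None,
    sg_window: int,
    sg_order: int,
) -> RamanSpectrum:
    s = baseline_subtract(s, baseline_order)
    return smooth_savgol(s, sg_window, sg_order)


def band_series_from_spectra(
    spectra: Sequence[RamanSpectrum],
    band: BandDefinition,
    baseline_order: int | None = None,
    sg_window: int = 11,
    sg_order: int = 3,
) -> BandTimeSeries:
    """Extract a raw band-intensity time series from treated spectra.

    Each spectrum is preprocessed (baseline, then smoothing) identically
    before peak extraction; spectra must be sorted by strictly increasing
    treatment time and share one depth.
    """
    if not spectra:
        raise AlignmentError("no spectra supplied")
    depths = {s.depth_um for s in spectra}
    if len(depths) > 1:
        raise AlignmentError(f"mixed depths in one series: {sorted(depths)}")
    times, values = [], []
    for s in spectra:
        if s.time_s is None:
            raise AlignmentError("untreated spectrum in a treated time series")
        proc = _preprocess(s, baseline_order, sg_window, sg_order)
        times.append(s.time_s)
        values.append(band_intensity(proc, band).intensity)
    return BandTimeSeries(
        spectra[0].depth_um, band, np.array(times), np.array(values), SeriesKind.RAW
    )


@dataclass(frozen=True)
class TrgcAnalysis:
    """Tidy clearing-kinetics table plus the per-band TRGC series."""

    table: pd.DataFrame  # depth_um, band_cm1, time_s, raw_intensity, oc_eff,
    #                      trgc_intensity, trgc_concentration_pct
    trgc_series: dict[float, dict[float, BandTimeSeries]]  # depth -> band -> series


def analyze_fp_experiment(
    untreated: Mapping[float, Sequence[RamanSpectrum]],
    treated: Mapping[float, Sequence[RamanSpectrum]],
    calibration: CalibrationModel,
    collagen_bands: Sequence[BandDefinition] = COLLAGEN_BANDS,
    glycerol_band: BandDefinition = GLYCEROL_BAND,
    baseline_order: int | None = None,
    sg_window: int = 11,
    sg_order: int = 3,
) -> TrgcAnalysis:
    """Run the full clearing-kinetics pipeline on a fingerprint experiment.

    ``untreated`` maps depth (um) to replicate reference spectra;
    ``treated`` maps depth to the time-ordered treated spectra.  The
    untreated replicates of each depth are averaged, preprocessed and
    used as that depth's ``I_0`` — references are per sample and depth,
    never pooled across depths.
    """
    rows = []
    all_series: dict[float, dict[float, BandTimeSeries]] = {}
    for depth, series_spectra in treated.items():
        ref = average_replicates(list(untreated[depth]))
        ref_proc = _preprocess(ref, baseline_order, sg_window, sg_order)
        refs = {
            b.center_cm1: band_intensity(ref_proc, b).intensity for b in collagen_bands
        }
        gly = band_series_from_spectra(
            series_spectra, glycerol_band, baseline_order, sg_window, sg_order
        )
        collagen = {
            b.center_cm1: band_series_from_spectra(
                series_spectra, b, baseline_order, sg_window, sg_order
            )
            for b in collagen_bands
        }
        all_series[depth] = build_trgc_series(gly, collagen, refs, calibration)
        for center, col in collagen.items():
            eff = oc_efficiency(col.values, refs[center])
            corrected = trgc(gly.values, eff)
            conc = all_series[depth][center].values
            for i, t in enumerate(gly.times_s):
                rows.append(
                    {
                        "depth_um": depth,
                        "band_cm1": center,
                        "time_s": t,
                        "raw_intensity": col.values[i],
                        "oc_eff": eff[i],
                        "trgc_intensity": corrected[i],
                        "trgc_concentration_pct": conc[i],
                    }
                )
    return TrgcAnalysis(pd.DataFrame(rows), all_series)
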