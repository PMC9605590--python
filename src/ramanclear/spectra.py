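"""Spectrum data model, file I/O and the preprocessing chain.

A :class:`RamanSpectrum` is an immutable pairing of a strictly increasing
wavenumber axis (cm^-1) with intensity counts, tagged with acquisition
metadata: spectral region (fingerprint or high wavenumber), probing depth
below the tissue surface, and treatment time.  Untreated reference spectra
carry ``time_s=None`` rather than ``time_s=0`` so that "before agent
application" is distinguishable from "immediately after".

Preprocessing follows the usual confocal-Raman order: polynomial baseline
subtraction, Savitzky-Golay smoothing, and optional PCA denoising across a
set of spectra sharing one axis.  Band intensities are extracted as the
peak maximum inside a +/- half-window around the nominal band center.
"""

from __future__ import annotations

import enum

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import (
    AxisMismatchError,
    BandWindowError,
    DegenerateFitError,
    GroupingError,
    ParameterError,
    SpectrumParseError,
    SpectrumValidationError,
)

__all__ = [
    "Region",
    "RamanSpectrum",
    "BandDefinition",
    "BandIntensity",
    "COLLAGEN_BANDS",
    "GLYCEROL_BAND",
    "GLYCEROL_BANDS",
    "read_spectrum",
    "write_spectrum",
    "baseline_subtract",
    "estimate_baseline",
    "smooth_savgol",
    "pca_denoise",
    "average_replicates",
    "band_intensity",
    "resample_to_grid",
]


class Region(enum.Enum):
    """Spectral acquisition region."""

    FP = "FP"  # fingerprint, 400-1800 cm^-1
    HWN = "HWN"  # high wavenumber, 2600-3800 cm^-1


#: Allowed wavenumber span per region (cm^-1).
REGION_SPAN: dict[Region, tuple[float, float]] = {
    Region.FP: (400.0, 1800.0),
    Region.HWN: (2600.0, 3800.0),
}


@dataclass(frozen=True)
class RamanSpectrum:
    """One Raman spectrum with acquisition metadata.

    Parameters
    ----------
    wavenumbers
        Strictly increasing axis in cm^-1, length >= 2.
    intensities
        Counts, same length as ``wavenumbers``.
    region
        :class:`Region` of acquisition; the axis must lie inside the
        region's span.
    depth_um
        Probing depth below the surface in micrometres (>= 0).
    time_s
        Seconds since agent application, or ``None`` for an untreated
        reference.
    sample_id
        Opaque sample label.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    region: Region
    depth_um: float = 0.0
    time_s: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or y.ndim != 1:
            raise SpectrumValidationError("wavenumbers and intensities must be 1-D")
        if wn.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if wn.size != y.size:
            raise SpectrumValidationError(
                f"axis length {wn.size} != intensity length {y.size}"
            )
        if not np.all(np.diff(wn) > 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(y)):
            raise SpectrumValidationError("non-finite values in spectrum")
        lo, hi = REGION_SPAN[self.region]
        if wn[0] < lo - 1e-9 or wn[-1] > hi + 1e-9:
            raise SpectrumValidationError(
                f"{self.region.value} spectrum spans [{wn[0]:g}, {wn[-1]:g}] cm^-1, "
                f"outside the allowed [{lo:g}, {hi:g}]"
            )
        if self.depth_um < 0:
            raise SpectrumValidationError("depth_um must be >= 0")
        if self.time_s is not None and self.time_s < 0:
            raise SpectrumValidationError("time_s must be >= 0 or None (untreated)")
        wn.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    @property
    def is_untreated(self) -> bool:
        return self.time_s is None

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, y: np.ndarray) -> "RamanSpectrum":
        """Copy of this spectrum with new intensities on the same axis."""
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass(frozen=True)
class BandDefinition:
    """A Raman band: nominal center and extraction half-window (cm^-1)."""

    center_cm1: float
    half_window_cm1: float = 10.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.half_window_cm1 <= 0:
            raise SpectrumValidationError("half_window_cm1 must be > 0")


#: The five collagen reference bands used for clearing-efficiency tracking.
COLLAGEN_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition(938.0, 10.0, "C-C stretch (collagen backbone)"),
    BandDefinition(1003.0, 10.0, "phenylalanine ring breathing"),
    BandDefinition(1247.0, 10.0, "amide III"),
    BandDefinition(1270.0, 10.0, "amide III"),
    BandDefinition(1665.0, 10.0, "amide I"),
)

#: The least-overlapped glycerol marker band used for quantification.
GLYCEROL_BAND = BandDefinition(485.0, 10.0, "glycerol CCO rock")

#: All glycerol bands emulated by the synthetic generator.
GLYCEROL_BANDS: tuple[BandDefinition, ...] = (
    GLYCEROL_BAND,
    BandDefinition(849.0, 10.0, "glycerol C-C stretch"),
    BandDefinition(1054.0, 10.0, "glycerol C-O stretch"),
    BandDefinition(1466.0, 10.0, "glycerol CH2 bend"),
)


class BandIntensity(NamedTuple):
    """A band intensity together with the wavenumber where it was found."""

    intensity: float
    wavenumber_cm1: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectrum(
    path: str | Path,
    region: Region | str,
    depth_um: float = 0.0,
    time_s: float | None = None,
    sample_id: str = "",
) -> RamanSpectrum:
    """Read a two-column text spectrum (wavenumber, intensity).

    Tab, comma and whitespace delimiters are accepted; lines starting with
    ``#`` are comments.  Rows stored in descending wavenumber order are
    sorted ascending (intensities permuted consistently).

    Raises
    ------
    SpectrumParseError
        On malformed rows (the message names the 1-based line number) or
        fewer than two data points.
    """
    if isinstance(region, str):
        region = Region(region)
    path = Path(path)
    wns: list[float] = []
    ys: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected two columns, got {len(tokens)}"
                )
            try:
                wns.append(float(tokens[0]))
                ys.append(float(tokens[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value ({line!r})"
                ) from exc
    if len(wns) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data points")
    wn = np.asarray(wns)
    y = np.asarray(ys)
    order = np.argsort(wn, kind="stable")
    try:
        return RamanSpectrum(wn[order], y[order], region, depth_um, time_s, sample_id)
    except SpectrumValidationError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


def write_spectrum(s: RamanSpectrum, path: str | Path) -> None:
    """Write a spectrum as two tab-separated columns with a comment header."""
    path = Path(path)
    time_label = "untreated" if s.time_s is None else f"{s.time_s:g}"
    header = (
        f"# region={s.region.value} depth_um={s.depth_um:g} "
        f"time_s={time_label} sample_id={s.sample_id}\n"
        "# wavenumber_cm1\tintensity\n"
    )
    body = "\n".join(
        f"{w:.6g}\t{v:.10g}" for w, v in zip(s.wavenumbers, s.intensities)
    )
    path.write_text(header + body + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

_DEFAULT_BASELINE_ORDER = {Region.FP: 5, Region.HWN: 3}


def _rolling_lower_envelope(y: np.ndarray, window: int, q: float) -> np.ndarray:
    ser = pd.Series(y)
    return ser.rolling(window, center=True, min_periods=1).quantile(q).to_numpy()


def estimate_baseline(
    wavenumbers: np.ndarray,
    intensities: np.ndarray,
    poly_order: int,
    anchor_quantile: float = 0.1,
    max_iter: int = 30,
) -> np.ndarray:
    """Iterative lower-envelope polynomial baseline.

    Anchor points are seeded from a rolling lower-envelope quantile
    (fraction ``anchor_quantile`` of each window) so that peaks are
    excluded from the first fit; the anchor set is then re-estimated
    against the current fit (keeping points not significantly above it)
    until it stabilises.  On a pure polynomial input of degree <=
    ``poly_order`` the fit is exact, so the subtraction leaves ~0.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(intensities, dtype=float)
    n = y.size
    if poly_order < 0:
        raise ParameterError("poly_order must be >= 0")
    if not 0.0 < anchor_quantile <= 1.0:
        raise ParameterError("anchor_quantile must be in (0, 1]")
    if poly_order >= n - 1:
        raise DegenerateFitError(
            f"poly_order {poly_order} needs more than {poly_order + 1} points, got {n}"
        )
    scale = max(float(np.ptp(y)), 1e-300)
    tol = 1e-10 * scale

    window = max(2 * (poly_order + 2) + 1, n // 15)
    window = min(window | 1, n)  # odd, capped at n
    env = _rolling_lower_envelope(y, window, anchor_quantile)
    anchors = y <= env + tol
    if anchors.sum() < poly_order + 2:
        anchors = np.zeros(n, dtype=bool)
        anchors[np.argsort(y)[: poly_order + 2]] = True

    base = np.zeros(n)
    for _ in range(max_iter):
        fit = np.polynomial.Polynomial.fit(wn[anchors], y[anchors], poly_order)
        base = fit(wn)
        resid = y - base
        sigma = float(np.std(resid[anchors]))
        new_anchors = resid <= 2.5 * sigma + tol
        if new_anchors.sum() < poly_order + 2 or np.array_equal(new_anchors, anchors):
            break
        anchors = new_anchors
    return base


def baseline_subtract(
    s: RamanSpectrum,
    poly_order: int | None = None,
    anchor_quantile: float = 0.1,
) -> RamanSpectrum:
    """Subtract an iteratively fitted polynomial baseline.

    ``poly_order`` defaults to 5 for fingerprint spectra and 3 for
    high-wavenumber spectra.
    """
    if poly_order is None:
        poly_order = _DEFAULT_BASELINE_ORDER[s.region]
    base = estimate_baseline(s.wavenumbers, s.intensities, poly_order, anchor_quantile)
    return s.with_intensities(s.intensities - base)


def smooth_savgol(
    s: RamanSpectrum, window_points: int = 11, poly_order: int = 3
) -> RamanSpectrum:
    """Savitzky-Golay smoothing (defaults: 11-point window, 3rd order)."""
    if window_points % 2 == 0:
        raise ParameterError(f"window_points must be odd, got {window_points}")
    if window_points <= poly_order:
        raise ParameterError(
            f"window_points ({window_points}) must exceed poly_order ({poly_order})"
        )
    if window_points > len(s):
        raise ParameterError(
            f"window_points ({window_points}) exceeds spectrum length ({len(s)})"
        )
    y = savgol_filter(s.intensities, window_points, poly_order, mode="interp")
    return s.with_intensities(y)


def _check_common_axis(spectra: Sequence[RamanSpectrum]) -> np.ndarray:
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != axis.shape or not np.array_equal(
            s.wavenumbers, axis
        ):
            raise AxisMismatchError("spectra do not share a common wavenumber axis")
    return axis


def pca_denoise(
    spectra: Sequence[RamanSpectrum], n_components: int = 3
) -> list[RamanSpectrum]:
    """Reconstruct each spectrum from the leading principal components.

    The spectra (rows) are mean-centered, decomposed by PCA, and rebuilt
    from the top ``n_components`` components, discarding low-variance
    directions that are dominated by noise.
    """
    spectra = list(spectra)
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    if len(spectra) < n_components + 1:
        raise ParameterError(
            f"need at least {n_components + 1} spectra for "
            f"{n_components} components, got {len(spectra)}"
        )
    _check_common_axis(spectra)
    from sklearn.decomposition import PCA

    X = np.vstack([s.intensities for s in spectra])
    pca = PCA(n_components=n_components, svd_solver="full")
    X_hat = pca.inverse_transform(pca.fit_transform(X))
    return [s.with_intensities(row) for s, row in zip(spectra, X_hat)]


def average_replicates(spectra: Sequence[RamanSpectrum]) -> RamanSpectrum:
    """Pointwise mean of replicate spectra sharing region, depth and time."""
    spectra = list(spectra)
    if not spectra:
        raise GroupingError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.region is not first.region:
            raise GroupingError("cannot average spectra from different regions")
        if s.depth_um != first.depth_um:
            raise GroupingError("cannot average spectra from different depths")
        if s.time_s != first.time_s:
            raise GroupingError("cannot average spectra from different time points")
    _check_common_axis(spectra)
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return first.with_intensities(mean)


def band_intensity(s: RamanSpectrum, band: BandDefinition) -> BandIntensity:
    """Peak maximum inside ``center +/- half_window`` and its position.

    The spectrum is expected to be baseline-corrected; the metric is the
    maximum intensity sample in the window, not an integrated area.
    """
    lo = band.center_cm1 - band.half_window_cm1
    hi = band.center_cm1 + band.half_window_cm1
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise BandWindowError(
            f"band window [{lo:g}, {hi:g}] cm^-1 does not overlap the "
            f"spectrum span [{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}]"
        )
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(s.intensities[idx])]
    return BandIntensity(float(s.intensities[best]), float(s.wavenumbers[best]))


def resample_to_grid(s: RamanSpectrum, grid: np.ndarray) -> RamanSpectrum:
    """Linear interpolation onto an explicit common grid.

    Interpolation is never applied implicitly elsewhere in the package;
    mismatched axes raise instead.  The target grid must lie inside the
    spectrum's span so no extrapolation occurs.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavenumbers[0] - 1e-9 or grid[-1] > s.wavenumbers[-1] + 1e-9:
        raise AxisMismatchError("target grid extends beyond the spectrum span")
    y = np.interp(grid, s.wavenumbers, s.intensities)
    return replace(s, wavenumbers=grid, intensities=y)
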