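"""Dataset layout on disk: spectrum files plus a manifest CSV.

A dataset directory holds plain-text two-column spectrum files and a
``manifest.csv`` mapping each file to its metadata (sample_id, region,
depth_um, time_s; an empty time_s marks an untreated reference).  A
calibration series uses a separate manifest with columns
``concentration_pct, spectrum_path``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import SpectrumParseError
from .spectra import RamanSpectrum, Region, read_spectrum, write_spectrum

__all__ = [
    "write_dataset",
    "read_dataset",
    "group_by_depth",
    "write_calibration_dataset",
    "read_calibration_dataset",
]

MANIFEST_COLUMNS = ["path", "sample_id", "region", "depth_um", "time_s"]


def write_dataset(
    spectra: Sequence[RamanSpectrum],
    directory: str | Path,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write spectra and their manifest; returns the manifest path."""
    directory = Path(directory)
    (directory / "spectra").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(spectra):
        fname = f"spectra/{i:04d}_{s.sample_id or 'spectrum'}.txt"
        write_spectrum(s, directory / fname)
        rows.append(
            {
                "path": fname,
                "sample_id": s.sample_id,
                "region": s.region.value,
                "depth_um": s.depth_um,
                "time_s": "" if s.time_s is None else s.time_s,
            }
        )
    manifest = directory / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> list[RamanSpectrum]:
    """Read every spectrum listed in a manifest CSV (paths are relative)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"time_s": "object"})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise SpectrumParseError(
            f"{manifest_path}: manifest missing columns {sorted(missing)}"
        )
    base = manifest_path.parent
    out = []
    for _, row in df.iterrows():
        t_raw = row["time_s"]
        time_s = None if pd.isna(t_raw) or str(t_raw).strip() == "" else float(t_raw)
        out.append(
            read_spectrum(
                base / str(row["path"]),
                Region(str(row["region"])),
                depth_um=float(row["depth_um"]),
                time_s=time_s,
                sample_id=str(row["sample_id"]),
            )
        )
    return out


def group_by_depth(
    spectra: Sequence[RamanSpectrum], region: Region
) -> tuple[dict[float, list[RamanSpectrum]], dict[float, list[RamanSpectrum]]]:
    """Split one region's spectra into (untreated, treated-by-time) per depth."""
    untreated: dict[float, list[RamanSpectrum]] = {}
    treated: dict[float, list[RamanSpectrum]] = {}
    for s in spectra:
        if s.region is not region:
            continue
        target = untreated if s.time_s is None else treated
        target.setdefault(s.depth_um, []).append(s)
    for depth in treated:
        treated[depth].sort(key=lambda s: s.time_s)
    return untreated, treated


def write_calibration_dataset(
    standards: Sequence[tuple[float, RamanSpectrum]],
    directory: str | Path,
    manifest_name: str = "calibration.csv",
) -> Path:
    directory = Path(directory)
    (directory / "calibration").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (conc, s) in enumerate(standards):
        fname = f"calibration/{i:04d}_{s.sample_id or 'standard'}.txt"
        write_spectrum(s, directory / fname)
        rows.append({"concentration_pct": conc, "spectrum_path": fname})
    manifest = directory / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_calibration_dataset(
    manifest_path: str | Path,
) -> list[tuple[float, RamanSpectrum]]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("concentration_pct", "spectrum_path"):
        if col not in df.columns:
            raise SpectrumParseError(f"{manifest_path}: missing column {col!r}")
    base = manifest_path.parent
    return [
        (
            float(row["concentration_pct"]),
            read_spectrum(base / str(row["spectrum_path"]), Region.FP),
        )
        for _, row in df.iterrows()
    ]
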