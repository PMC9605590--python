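"""Pipeline configuration: YAML-backed, validated on construction."""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["PipelineConfig", "load_synthetic_spec"]


@dataclass(frozen=True)
class PipelineConfig:
    """Frozen per-run analysis parameters.

    Every spectrum in a run is preprocessed identically with these
    settings; defaults follow common confocal-Raman practice (11-point
    3rd-order Savitzky-Golay, 3 principal components, 90 s "after"
    summary time).
    """

    baseline_order_fp: int = 5
    baseline_order_hwn: int = 2
    anchor_quantile: float = 0.1
    sg_window: int = 11
    sg_order: int = 3
    pca_components: int = 3
    band_half_window_cm1: float = 10.0
    after_time_s: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_order_fp < 0:
            raise ConfigError("baseline_order_fp: must be >= 0")
        if self.baseline_order_hwn < 0:
            raise ConfigError("baseline_order_hwn: must be >= 0")
        if not 0.0 < self.anchor_quantile <= 1.0:
            raise ConfigError("anchor_quantile: must be in (0, 1]")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ConfigError("sg_window: must be odd and exceed sg_order")
        if self.pca_components < 1:
            raise ConfigError("pca_components: must be >= 1")
        if self.band_half_window_cm1 <= 0:
            raise ConfigError("band_half_window_cm1: must be > 0")
        if self.after_time_s < 0:
            raise ConfigError("after_time_s: must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


_SPEC_SCALAR_FIELDS = {
    "seed", "noise_cv", "noise_floor", "glycerol_response", "band_sigma_cm1",
    "fp_step_cm1", "hwn_step_cm1", "n_untreated_replicates",
}
_SPEC_LIST_FIELDS = {"depths_um", "times_s", "baseline_coeffs"}
_SPEC_MAP_FIELDS = {"true_D", "true_C0", "collagen_amplitudes"}


def load_synthetic_spec(path: str | Path):
    """Build a :class:`~ramanclear.synth.SyntheticExperimentSpec` from YAML.

    Unknown fields and invalid values raise :class:`ConfigError` naming
    the offending field.  ``oc_gain`` entries are mappings
    ``{depth: {g_max: ..., tau_s: ...}}``.
    """
    from .exceptions import ParameterError
    from .synth import OCGain, SyntheticExperimentSpec

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SPEC_SCALAR_FIELDS:
            kwargs[key] = value
        elif key in _SPEC_LIST_FIELDS:
            kwargs[key] = tuple(float(v) for v in value)
        elif key in _SPEC_MAP_FIELDS:
            kwargs[key] = {float(k): float(v) for k, v in value.items()}
        elif key == "oc_gain":
            try:
                kwargs[key] = {
                    float(k): OCGain(float(v["g_max"]), float(v["tau_s"]))
                    for k, v in value.items()
                }
            except (KeyError, TypeError, ParameterError) as exc:
                raise ConfigError(f"oc_gain: {exc}") from exc
        else:
            raise ConfigError(f"unknown synthetic-spec field: {key}")
    try:
        return SyntheticExperimentSpec(**kwargs)
    except (ParameterError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
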