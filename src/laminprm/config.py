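"""Default analysis settings, overridable from a YAML file or CLI flags."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = ["QuantConfig", "load_config"]


@dataclass(frozen=True)
class QuantConfig:
    """Settings of the extraction/quantification stage.

    tol_ppm
        XIC m/z tolerance in ppm, applied at every selection level and to
        the monitored ion (Orbitrap-class accuracy).
    integration
        ``trapezoid`` (over the scheduled RT window) or ``peak``
        (local-maximum bounded).
    loq_ratio
        light/heavy ratio below which an analyte counts as detected but not
        quantifiable.
    noise_floor_area
        integrated-area threshold separating absence from detection.
    reference_symbol / reference_scale
        relative mode normalizes areas so the reference maps to the scale.
    """

    tol_ppm: float = 10.0
    integration: str = "trapezoid"
    loq_ratio: float = 0.01
    noise_floor_area: float = 200.0
    reference_symbol: str = "IC"
    reference_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.integration not in ("trapezoid", "peak"):
            raise ValueError("integration must be 'trapezoid' or 'peak'")


def packaged_defaults_path() -> Path:
    """The YAML file the default settings are read from (shipped with the
    package; a single place to inspect or copy as an override template)."""
    from importlib import resources

    return Path(str(resources.files("laminprm.data") / "defaults.yaml"))


def load_config(path: str | Path | None = None, **overrides) -> QuantConfig:
    """Build a config from the packaged defaults, an optional YAML file,
    then keyword overrides (unknown keys are rejected)."""
    defaults = packaged_defaults_path()
    cfg = QuantConfig()
    if defaults.exists():
        cfg = _apply(cfg, yaml.safe_load(defaults.read_text()) or {}, str(defaults))
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _apply(cfg, data, source=str(path))
    if overrides:
        cfg = _apply(cfg, overrides, source="overrides")
    return cfg


def _apply(cfg: QuantConfig, data: dict, source: str) -> QuantConfig:
    known = {f.name for f in fields(QuantConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {source}: {sorted(unknown)}")
    return replace(cfg, **{k: v for k, v in data.items() if v is not None})
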