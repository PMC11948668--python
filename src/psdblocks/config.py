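"""Strictly validated YAML run configuration.

Unknown keys are errors: silent misconfiguration of a threshold fraction or
a DBSCAN radius is worse than a hard failure.  Defaults are the study
operating points: a 40-nm slab, bottom-25% below-background thresholding,
DBSCAN (eps = 6 px, min_pts = 32), nearest-centroid pairing, 100
randomization replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["ThresholdConfig", "DbscanConfig", "RandomizationConfig", "AnalyzeConfig", "load_analyze_config"]


@dataclass
class ThresholdConfig:
    fraction: float = 0.25
    mode: str = "below_background_fraction"

    def validate(self):
        if not (0 < self.fraction <= 1):
            raise ConfigError(f"threshold.fraction must be in (0, 1], got {self.fraction}")
        from .slab import THRESHOLD_MODES

        if self.mode not in THRESHOLD_MODES:
            raise ConfigError(f"threshold.mode must be one of {THRESHOLD_MODES}, got {self.mode!r}")


@dataclass
class DbscanConfig:
    eps: float = 6.0
    eps_units: str = "px"  # "px" or "nm" (converted by voxel size at run time)
    min_pts: int = 32

    def validate(self):
        if self.eps <= 0:
            raise ConfigError(f"dbscan.eps must be > 0, got {self.eps}")
        if self.eps_units not in ("px", "nm"):
            raise ConfigError(f"dbscan.eps_units must be 'px' or 'nm', got {self.eps_units!r}")
        if self.min_pts < 1:
            raise ConfigError(f"dbscan.min_pts must be >= 1, got {self.min_pts}")


@dataclass
class RandomizationConfig:
    reps: int = 100
    seed: int = 0
    domain: str = "hull"

    def validate(self):
        if self.reps < 1:
            raise ConfigError(f"randomization.reps must be >= 1, got {self.reps}")
        if self.domain not in ("hull", "pixels"):
            raise ConfigError(f"randomization.domain must be 'hull' or 'pixels', got {self.domain!r}")


@dataclass
class AnalyzeConfig:
    volume: str = ""
    annotations: str = ""
    output_dir: str = "psdblocks_out"
    slab_depth: float = 40.0
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    dbscan: DbscanConfig = field(default_factory=DbscanConfig)
    pairing_mode: str = "nearest_centroid"
    randomization: RandomizationConfig = field(default_factory=RandomizationConfig)

    def validate(self):
        if not self.volume:
            raise ConfigError("config key 'volume' (MRC path) is required")
        if not self.annotations:
            raise ConfigError("config key 'annotations' (CSV path) is required")
        if self.slab_depth <= 0:
            raise ConfigError(f"slab_depth must be > 0, got {self.slab_depth}")
        if self.pairing_mode not in ("nearest_centroid", "all_pairs"):
            raise ConfigError(f"pairing_mode must be 'nearest_centroid' or 'all_pairs', got {self.pairing_mode!r}")
        self.threshold.validate()
        self.dbscan.validate()
        self.randomization.validate()


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        val = data[name]
        if f.type in ("ThresholdConfig", "DbscanConfig", "RandomizationConfig"):
            sub_cls = {"threshold": ThresholdConfig, "dbscan": DbscanConfig, "randomization": RandomizationConfig}[name]
            if not isinstance(val, dict):
                raise ConfigError(f"config key {name!r} must be a mapping")
            val = _build(sub_cls, val, f"{path}{name}.")
        kwargs[name] = val
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid config: {exc}") from exc


def load_analyze_config(path) -> AnalyzeConfig:
    """Parse + strictly validate an analysis config YAML file."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = _build(AnalyzeConfig, data, "")
    cfg.validate()
    return cfg
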