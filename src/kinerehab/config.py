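"""YAML-backed pipeline configuration.

Flat dataclasses mirroring the tunables of each processing stage; any
subset may be overridden from a YAML file with the same nesting, e.g.::

    activity:
      threshold_pct: 30
      window_s: 0.5
    ssa:
      n_components: 12
      f_trend_hz: 0.1
    camera_fixed: true
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ActivityConfig", "SSAConfig", "SmoothingConfig", "PeriodConfig",
           "CropConfig", "GuidelineConfig", "PipelineConfig"]


@dataclass
class ActivityConfig:
    threshold_pct: float = 30.0
    window_s: float = 0.5
    min_active_s: float = 0.5
    min_pause_s: float = 2.0
    min_motion: float = 0.02


@dataclass
class SSAConfig:
    window: int | None = None
    n_components: int = 12
    f_trend_hz: float = 0.1
    e_noise: float = 0.01


@dataclass
class SmoothingConfig:
    half_window: int = 4


@dataclass
class PeriodConfig:
    min_s: float = 0.5
    max_s: float = 10.0


@dataclass
class CropConfig:
    scale: float = 2.0
    calib_window_s: float = 1.0
    vis_min: float = 0.5


@dataclass
class GuidelineConfig:
    tolerance: float = 0.15


@dataclass
class PipelineConfig:
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    ssa: SSAConfig = field(default_factory=SSAConfig)
    ma: SmoothingConfig = field(default_factory=SmoothingConfig)
    period: PeriodConfig = field(default_factory=PeriodConfig)
    crop: CropConfig = field(default_factory=CropConfig)
    guidelines: GuidelineConfig = field(default_factory=GuidelineConfig)
    camera_fixed: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, val in raw.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            cur = getattr(cfg, section)
            if isinstance(val, dict):
                for k, v in val.items():
                    if not hasattr(cur, k):
                        raise KeyError(f"unknown config key {section}.{k}")
                    setattr(cur, k, v)
            else:
                setattr(cfg, section, val)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
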