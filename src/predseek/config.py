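"""Pipeline configuration: thresholds, window rule, generator preset, seed.

A single YAML file governs every stage; command-line flags override file
values, and the effective configuration is echoed to a provenance JSON so a
run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # test-battery thresholds
    r2_min: float = 0.9
    alpha: float = 0.05
    min_cr: float = 0.5
    # dynamic-regression window rule
    start_fraction: float = 0.5
    stride: int = 1
    # regression options
    intercept: bool = False
    r2_convention: str = "uncentered"
    # correlation options
    min_window: int = 3
    sd_ddof: int = 0  # 0 = population band, 1 = sample
    # generator
    preset: str = "predation"  # or "single-factor"
    n_regions: int = 32
    n_days: int = 61
    heterogeneity: float = 0.06
    sigma_frac: float = 0.005
    cr_pooling: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r2_min", "alpha", "min_cr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"config field {name} must lie in (0, 1), got {v}")
        if self.min_window < 3:
            raise ValueError("config field min_window must be at least 3")
        if self.n_regions < 1:
            raise ValueError("config field n_regions must be at least 1")
        if self.n_days < 4:
            raise ValueError("config field n_days must be at least 4")
        if self.preset not in ("predation", "single-factor"):
            raise ValueError("config field preset must be 'predation' or 'single-factor'")
        if self.sigma_frac < 0 or self.heterogeneity < 0:
            raise ValueError("config fields sigma_frac and heterogeneity must be nonnegative")
        if self.stride < 1:
            raise ValueError("config field stride must be a positive integer")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Overrides with value ``None`` are ignored, so CLI flags can default to
    "not given".
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a mapping of fields")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig.from_dict(data)
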