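"""Study configuration: factor levels, replication count, seeds and method
settings, loadable from YAML or JSON.  Validation happens before any
computation so a rejected configuration produces no partial outputs."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cutpoints import METHODS, EstimateSettings, GASettings
from .simulate import DEFAULT_BETAS, DEFAULT_FACTOR_LEVELS

__all__ = ["StudyConfig"]


@dataclass(frozen=True)
class StudyConfig:
    distributions: tuple[str, ...] = DEFAULT_FACTOR_LEVELS["distributions"]
    theta: tuple[float, ...] = DEFAULT_FACTOR_LEVELS["theta"]
    n_obs: tuple[int, ...] = DEFAULT_FACTOR_LEVELS["n_obs"]
    pc_t: tuple[float, ...] = DEFAULT_FACTOR_LEVELS["pc_t"]
    pc_f: tuple[float, ...] = DEFAULT_FACTOR_LEVELS["pc_f"]
    betas: tuple[float, float, float, float] = DEFAULT_BETAS
    n_sim: int = 500
    master_seed: int = 0
    methods: tuple[str, ...] = METHODS
    min_prop: float = 0.10
    ga: GASettings = field(default_factory=GASettings)
    workers: int = 1

    def __post_init__(self) -> None:
        for name in ("distributions", "theta", "n_obs", "pc_t", "pc_f", "methods"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if len(set(vals)) != len(vals):
                raise ValueError(f"{name} has duplicate entries")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.n_sim < 2:
            raise ValueError("n_sim must be at least 2")
        if not (0.0 < self.min_prop < 0.5):
            raise ValueError("min_prop must lie in (0, 0.5)")
        if self.workers < 1:
            raise ValueError("workers must be at least 1")
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if len(self.betas) != 4:
            raise ValueError("betas must have four entries")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "StudyConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        if "ga" in raw and isinstance(raw["ga"], Mapping):
            raw["ga"] = GASettings(**raw["ga"])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(raw, Mapping):
            raise ValueError(f"configuration file {path} is not a mapping")
        return cls.from_dict(raw)

    def factor_levels(self) -> dict:
        return {
            "distributions": self.distributions,
            "theta": self.theta,
            "n_obs": self.n_obs,
            "pc_t": self.pc_t,
            "pc_f": self.pc_f,
            "betas": self.betas,
            "master_seed": self.master_seed,
        }

    def estimate_settings(self) -> EstimateSettings:
        return EstimateSettings(min_prop=self.min_prop, ga=self.ga)

    def to_dict(self) -> dict:
        return asdict(self)
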