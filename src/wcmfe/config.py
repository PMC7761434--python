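"""Run configuration: defaults, JSON/YAML loading, hashing.

All algorithm defaults equal the selections used throughout the package:
tau_max=7, m=2, n=2, r=0.15 (of the cropped channel SD), weight mode h=3,
analysis interval [450, 900] (1-based inclusive samples at 128 Hz), 10x10-fold
cross-validation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import NetConfig
from .io import config_hash
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for the CLI pipeline."""

    seed: int = 0
    tau_max: int = 7
    m: int = 2
    n: float = 2.0
    r: float = 0.15
    h: int = 3
    interval: tuple = (450, 900)
    k: int = 10
    repeats: int = 10
    sim: SimConfig = field(default_factory=SimConfig)
    net: NetConfig = field(default_factory=NetConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interval"] = list(self.interval)
        d["sim"]["channels"] = list(self.sim.channels)
        d["sim"]["band"] = list(self.sim.band)
        d["sim"]["mu_band"] = list(self.sim.mu_band)
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("channels", "band", "mu_band"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if "net" in d and isinstance(d["net"], dict):
            d["net"] = NetConfig(**d["net"])
        if "interval" in d:
            d["interval"] = tuple(d["interval"])
        return cls(**d)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a .json or .yaml/.yml file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.from_dict(data or {})


def dump_config(cfg: RunConfig) -> str:
    """Serialise a RunConfig to pretty JSON."""
    return json.dumps(cfg.to_dict(), indent=2, sort_keys=True)
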