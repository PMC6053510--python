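"""Run configuration: defaults, YAML overrides, provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .calibration import DEFAULT_GRID
from .errors import ConfigError
from .preprocess import BoutConfig, FilterSpec


@dataclass
class RunConfig:
    """All tunables of the pipeline commands, with package defaults.

    A YAML config file overrides defaults section by section; CLI flags
    override the file. ``seed`` feeds every source of randomness.
    """

    rate: float = 100.0
    max_gap: float = 1.0
    filter_order: int = 4
    filter_cutoff: float = 20.0
    bout: BoutConfig = field(default_factory=BoutConfig)
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    daytime: tuple[float, float] = (7.0, 22.0)
    seed: int = 0

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(order=self.filter_order, cutoff=self.filter_cutoff)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["daytime"] = list(self.daytime)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults, a YAML file, and overrides."""
    cfg = RunConfig()
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
    pre = doc.get("preprocess", {})
    cfg.rate = float(pre.get("rate", cfg.rate))
    cfg.max_gap = float(pre.get("max_gap", cfg.max_gap))
    cfg.filter_order = int(pre.get("filter_order", cfg.filter_order))
    cfg.filter_cutoff = float(pre.get("filter_cutoff", cfg.filter_cutoff))
    if "bout" in pre:
        cfg.bout = BoutConfig(**{**asdict(cfg.bout), **pre["bout"]})
    cal = doc.get("calibration", {})
    if "grid" in cal:
        cfg.grid = {**cfg.grid, **cal["grid"]}
    mon = doc.get("monitor", {})
    if "daytime" in mon:
        lo, hi = mon["daytime"]
        cfg.daytime = (float(lo), float(hi))
    if "seed" in doc:
        cfg.seed = int(doc["seed"])
    for key, val in (overrides or {}).items():
        if val is not None:
            setattr(cfg, key, val)
    return cfg
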