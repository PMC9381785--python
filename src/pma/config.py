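"""Run configuration: a single seeded, fully declarative description of a run."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    seed: int = 0
    scale: float = 0.01
    region: Dict = field(default_factory=dict)
    population_counts: Optional[Dict[str, int]] = None
    catalogue_path: Optional[str] = None
    probability_table_path: Optional[str] = None
    out_dir: str = "pma_out"
    sigma_frac: float = 0.10
    simulate: bool = False
    export_hdf5: bool = False
    slice_thickness_um: float = 500.0
    stim_radius_um: float = 100.0
    sim_duration_ms: float = 40.0
    sim_params: Dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        if not 0 < self.scale <= 1:
            raise ConfigError("scale must be in (0, 1]")
        for name in ("catalogue_path", "probability_table_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} does not exist: {path}")

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed (stable fan-out from `seed`)."""
        stages = ("place", "morph", "connect", "analyze", "simulate")
        if stage not in stages:
            raise ConfigError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([int(self.seed), stages.index(stage)])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
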