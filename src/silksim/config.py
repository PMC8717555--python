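"""Pipeline configuration, seed derivation and config hashing.

All randomness flows from one global seed; each pipeline stage derives a named child
seed deterministically, so any stage can be reproduced in isolation.  Output files
embed a short hash of the resolved configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "child_seed", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    pass


def child_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (below 2^31) from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


_KNOWN_TOP = {"builder", "hydration", "dynamics", "analysis", "output_dir",
              "seed", "log_level"}
_KNOWN_SUB = {
    "builder": {"cell", "chains", "repeats", "template", "geometry_table"},
    "hydration": {"n_waters", "min_dist", "seed", "max_attempts_per_water"},
    "dynamics": {"mode", "d0_cm2_s", "ea_kj_mol", "d_direct_cm2_s", "temperatures_k",
                 "axis_fractions", "dt_ps", "n_steps", "sampling_stride", "n_waters"},
    "analysis": {"regions_file", "bin_width", "msd_max_lag", "msd_origin_stride",
                 "fit_window", "voxel"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (strict keys; referenced files must exist)."""

    builder: dict = field(default_factory=dict)
    hydration: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    output_dir: str = "silksim_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _KNOWN_SUB.items():
            sub = raw.get(section) or {}
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
        cfg = cls(**{k: raw[k] for k in raw})
        for key in ("geometry_table",):
            p = cfg.builder.get(key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"builder.{key}: file not found: {p}")
        p = cfg.analysis.get("regions_file")
        if p is not None and not Path(p).exists():
            raise ConfigError(f"analysis.regions_file: file not found: {p}")
        return cfg

    def to_dict(self) -> dict:
        return {"builder": self.builder, "hydration": self.hydration,
                "dynamics": self.dynamics, "analysis": self.analysis,
                "output_dir": self.output_dir, "seed": self.seed,
                "log_level": self.log_level}

    def hash(self) -> str:
        return config_hash(self.to_dict())

    def stage_seed(self, stage: str) -> int:
        return child_seed(self.seed, stage)
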