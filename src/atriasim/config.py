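"""Run configuration: a YAML-serializable description of one experiment.

A config plus the package version determines every output bit of the
deterministic stages. The master seed expands into per-stage/per-episode
child seeds through ``numpy.random.SeedSequence`` spawn keys
(``seed_for(master, stage, index)``), so scans are reproducible and
individual episodes can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "seed_for"]

_STAGE_IDS = {"geometry": 1, "pacing": 2, "restitution": 3, "scan": 4,
              "analysis": 5}


@dataclass
class RunConfig:
    # geometry: kind in {"cable", "sheet", "surrogate"} + its parameters
    geometry: dict = field(default_factory=lambda: {
        "kind": "cable", "n_nodes": 240, "region": "bulk"})
    # remodeling grid
    f_E_levels: list = field(default_factory=lambda: [0.0])
    s_levels: list = field(default_factory=lambda: [1.0])
    # protocol parameters
    protocol: dict = field(default_factory=lambda: {
        "kind": "pacing", "cycle_length": 1000.0, "n_beats": None,
        "until_steady": True})
    # solver settings
    dt: float = 0.01
    dx: float = 0.025
    episode_cap: float = 10_000.0
    # analysis settings
    frame_dt: float = 10.0
    merge_radius: float = 0.5
    apd_threshold: float = -70.0
    tip_threshold: float = -30.0
    term_voltage: float = -60.0
    term_quiet: float = 200.0
    n_recording_sites: int = 16
    # provenance
    master_seed: int = 1
    outdir: str = "runs"

    def validate(self) -> None:
        if self.geometry.get("kind") not in {"cable", "sheet", "surrogate"}:
            raise ValueError(f"unknown geometry kind {self.geometry.get('kind')!r}")
        for f_E in self.f_E_levels:
            if not 0.0 <= f_E <= 1.0:
                raise ValueError(f"f_E level {f_E} outside [0, 1]")
        for s in self.s_levels:
            if not 0.0 < s <= 1.0:
                raise ValueError(f"s level {s} outside (0, 1]")
        if self.dt <= 0 or self.dx <= 0 or self.episode_cap <= 0:
            raise ValueError("dt, dx and episode_cap must be positive")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def seed_for(master: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed (< 2**31) for a stage/index pair."""
    sid = _STAGE_IDS.get(stage)
    if sid is None:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master), sid, int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))
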