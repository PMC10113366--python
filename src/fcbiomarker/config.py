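"""Structured run configuration.

One YAML/JSON file drives every pipeline stage.  Unknown keys are rejected
with a suggestion; omitted keys take the defaults below (band 0.008–0.1 Hz,
FD threshold 0.5 mm, the 5×5 selection geometry, and so on).  A single
master seed is split deterministically per stage so individual stages can be
re-run reproducibly.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .crossval import CVConfig
from .scca import SCCAParams
from .slr import TrainOptions
from .synthcohort import CohortSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "stage_seed"]


class ConfigError(ValueError):
    pass


@dataclass
class PrepConfig:
    low_hz: float = 0.008
    high_hz: float = 0.1
    fd_threshold_mm: float = 0.5
    fd_radius_mm: float = 50.0
    filter_order: int = 2
    scrub_neighbors: int = 0


@dataclass
class CVOptions:
    n_perm: int = 100
    statistic: str = "accuracy"
    threshold: float = 0.5
    identify_rule: str = "ard"            # or "frequency"
    min_selection_fraction: float = 0.5   # used by the frequency rule


@dataclass
class ReportOptions:
    n_tests: int = 8
    fc_scale: str = "fisher_z"    # scale used for clinical correlations


@dataclass
class PathsConfig:
    workdir: str = "."


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    prep: PrepConfig = field(default_factory=PrepConfig)
    scca: SCCAParams = field(default_factory=SCCAParams)
    slr: TrainOptions = field(default_factory=TrainOptions)
    cv: CVOptions = field(default_factory=CVOptions)
    report: ReportOptions = field(default_factory=ReportOptions)
    seed: int = 0

    def cv_config(self) -> CVConfig:
        return CVConfig(scca=self.scca, slr=self.slr, seed=stage_seed(self.seed, "cv"),
                        threshold=self.cv.threshold)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=_jsonable)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from the master seed (< 2**31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _apply_section(obj, section: dict, path: str) -> None:
    valid = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in section.items():
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {path}{key!r}{suggestion}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"{path}{key} must be a mapping")
            _apply_section(current, value, f"{path}{key}.")
        else:
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(value)
            if isinstance(value, list):
                value = [_deep_tuple(v) if isinstance(v, list) else v for v in value]
            setattr(obj, key, value)


def _deep_tuple(v):
    return tuple(_deep_tuple(x) if isinstance(x, list) else x for x in v)


def load_config(path) -> RunConfig:
    """Read a YAML (or JSON) config, fill defaults, reject unknown keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    _apply_section(cfg, raw, "")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    d = json.loads(json.dumps(cfg.to_dict(), default=_jsonable))
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
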