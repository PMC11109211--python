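"""Run configuration: YAML loading, strict validation, defaults.

A config file is a flat YAML document with optional sections::

    mode: benchmark            # simulate | benchmark | report
    seed: 42
    out_dir: results/
    synthetic:                 # SyntheticSpec fields
      n_samples: 200
      balance: 3
    resamplers: [smote, random_undersampling]
    cv: {n_folds: 5, n_repeats: 30}
    grid:                      # ModelGrid overrides
      scorers: [anova, bhattacharyya]
    simulation:
      B_grid: [100, 50, 25]
      N_grid: [100]
      repeats: 100

Unknown keys are rejected with the offending key named, so typos fail loudly
before any compute starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .datasets import SyntheticSpec
from .modeling import ModelGrid
from .protocol import CVScheme
from .resamplers import METHODS, canonical_method
from .simulation import DEFAULT_B_GRID, DEFAULT_N_GRID

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]

_MODES = ("simulate", "benchmark", "report")


class ConfigError(ValueError):
    """A config file violates the schema."""


@dataclass
class RunConfig:
    mode: str = "benchmark"
    seed: int = 0
    out_dir: str = "results"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    resamplers: tuple = ("smote", "random_undersampling")
    cv: CVScheme = field(default_factory=CVScheme)
    grid: ModelGrid = field(default_factory=ModelGrid.reduced)
    sim_B_grid: tuple = DEFAULT_B_GRID
    sim_N_grid: tuple = DEFAULT_N_GRID
    sim_repeats: int = 100

    def as_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "synthetic": asdict(self.synthetic),
            "resamplers": list(self.resamplers),
            "cv": asdict(self.cv),
            "grid": asdict(self.grid),
            "simulation": {
                "B_grid": list(self.sim_B_grid),
                "N_grid": list(self.sim_N_grid),
                "repeats": self.sim_repeats,
            },
        }
        return d


def _check_keys(section: dict, allowed, where: str):
    unknown = sorted(set(section) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(unknown)}")


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML config; an empty file yields all
    defaults.  Bad resampler names list the known spellings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(
        raw,
        ("mode", "seed", "out_dir", "synthetic", "resamplers", "cv", "grid", "simulation"),
        "config root",
    )
    cfg = RunConfig()
    if "mode" in raw:
        if raw["mode"] not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}")
        cfg.mode = raw["mode"]
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])
    if "synthetic" in raw:
        sec = raw["synthetic"] or {}
        _check_keys(sec, [f.name for f in SyntheticSpec.__dataclass_fields__.values()], "synthetic")
        try:
            cfg.synthetic = SyntheticSpec(**sec)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"invalid synthetic spec: {e}") from e
    if "resamplers" in raw:
        names = raw["resamplers"]
        if isinstance(names, str):
            names = [names]
        try:
            cfg.resamplers = tuple(canonical_method(n) for n in names)
        except ValueError as e:
            known = ", ".join(display for display, _ in METHODS.values())
            raise ConfigError(f"{e} (known: {known})") from e
    if "cv" in raw:
        sec = raw["cv"] or {}
        _check_keys(sec, ("n_folds", "n_repeats", "base_seed"), "cv")
        try:
            cfg.cv = CVScheme(**sec)
        except ValueError as e:
            raise ConfigError(f"invalid cv scheme: {e}") from e
    if "grid" in raw:
        sec = raw["grid"] or {}
        _check_keys(sec, [f.name for f in ModelGrid.__dataclass_fields__.values()], "grid")
        sec = {k: tuple(v) if isinstance(v, list) else v for k, v in sec.items()}
        try:
            cfg.grid = ModelGrid(**{**asdict(ModelGrid.reduced()), **sec})
        except ValueError as e:
            raise ConfigError(f"invalid model grid: {e}") from e
    if "simulation" in raw:
        sec = raw["simulation"] or {}
        _check_keys(sec, ("B_grid", "N_grid", "repeats"), "simulation")
        if "B_grid" in sec:
            cfg.sim_B_grid = tuple(float(b) for b in sec["B_grid"])
        if "N_grid" in sec:
            cfg.sim_N_grid = tuple(int(n) for n in sec["N_grid"])
        if "repeats" in sec:
            cfg.sim_repeats = int(sec["repeats"])
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved config back to YAML; load_config(save_config(c))
    round-trips to an equal config."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the fully resolved config: two runs with the same
    hash (and seed, which the hash includes) produce identical outputs."""
    blob = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
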