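"""Configuration files, result serialization, fixtures and run manifests.

Configurations are plain mappings mirroring :class:`raftsim.engine.SimConfig`
field names, read from YAML, JSON or TOML by extension.  Unknown keys are
rejected and every validation error names the offending field.  Runs are
written as CSV plus a JSON manifest carrying the config echo, the master
and per-replicate seeds, version, wall-times and per-file checksums --
enough to re-run and reproduce every output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import (
    ConfigError,
    DomainSpec,
    SimConfig,
    SimState,
    SummaryStat,
    init_state,
    replicate_seeds,
)
from .membrane import BoxSpec, MotionParams
from .reactions import ReactionParams

__all__ = [
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "dump_config",
    "write_run",
    "write_sweep",
    "make_fixture",
    "FIXTURE_NAMES",
]

_SECTION_TYPES = {
    "box": BoxSpec,
    "domains": DomainSpec,
    "motion": MotionParams,
    "reactions": ReactionParams,
}

FIXTURE_NAMES = ("tangent_pair", "default_47", "crowded_200", "two_domains")


def _build_section(name: str, cls, data: dict[str, Any]):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{name}'; "
            f"allowed: {sorted(allowed)}"
        )
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def config_from_dict(data: dict[str, Any] | None) -> SimConfig:
    """Validated SimConfig from a plain mapping; defaults fill gaps."""
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for key, cls in _SECTION_TYPES.items():
        if key in data:
            section = data.pop(key)
            if not isinstance(section, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(key, cls, section)
    allowed = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s): {sorted(unknown)}; "
            f"allowed: {sorted(allowed | set(_SECTION_TYPES))}"
        )
    kwargs.update(data)
    try:
        return SimConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: SimConfig) -> dict[str, Any]:
    """Plain-mapping echo of a SimConfig (round-trips exactly)."""
    return dataclasses.asdict(config)


def load_config(path: str | Path) -> SimConfig:
    """Read and validate a configuration file (YAML/JSON/TOML).

    An empty file yields the full default configuration.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif suffix == ".json":
        text = path.read_text()
        data = json.loads(text) if text.strip() else None
    else:  # YAML (also parses JSON)
        data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping in {path}")
    return config_from_dict(data)


def dump_config(config: SimConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _summary_frame(stats: dict[str, SummaryStat]) -> pd.DataFrame:
    rows = []
    for name, s in stats.items():
        if name.startswith("_"):
            continue
        rows.append({"observable": name, "mean": s.mean,
                     "sd": s.sd if s.sd is not None else np.nan,
                     "n_replicates": s.n_replicates})
    return pd.DataFrame(rows)


def write_run(out_dir: str | Path, config: SimConfig, series_by_seed: dict,
              stats: dict[str, SummaryStat],
              started: float | None = None) -> dict[str, str]:
    """Write timeseries.csv, summary.csv, config echo and manifest.json.

    Returns the file inventory (name -> sha256).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for seed, series in series_by_seed.items():
        df = series.to_dataframe()
        df.insert(0, "seed", seed)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "timeseries.csv", index=False)
    _summary_frame(stats).to_csv(out / "summary.csv", index=False)
    dump_config(config, out / "config.yaml")
    inventory = {
        name: _sha256(out / name)
        for name in ("timeseries.csv", "summary.csv", "config.yaml")
    }
    manifest = {
        "tool": "raftsim",
        "version": __version__,
        "master_seed": config.seed,
        "replicate_seeds": replicate_seeds(config),
        "config": config_to_dict(config),
        "started_unix": started,
        "finished_unix": time.time(),
        "files": inventory,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return inventory


def write_sweep(out_dir: str | Path, result, started: float | None = None
                ) -> dict[str, str]:
    """Write sweep.csv (tidy) plus manifest.json for a SweepResult."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.df.to_csv(out / "sweep.csv", index=False)
    inventory = {"sweep.csv": _sha256(out / "sweep.csv")}
    manifest = {
        "tool": "raftsim",
        "version": __version__,
        "preset": result.spec.preset_id if result.spec else None,
        "description": result.spec.description if result.spec else "",
        "master_seed": result.spec.base.seed if result.spec else None,
        "config": config_to_dict(result.spec.base) if result.spec else None,
        "varied": {k: list(map(float, v))
                   for k, v in (result.spec.varied if result.spec else {}).items()},
        "started_unix": started,
        "finished_unix": time.time(),
        "files": inventory,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return inventory


def make_fixture(name: str, seed: int = 0) -> SimState:
    """Deterministic named initial states for tests and demos."""
    rng = np.random.default_rng(seed)
    if name == "tangent_pair":
        cfg = SimConfig(n_receptor_monomers=2,
                        domains=DomainSpec(count=0, occupied_percent=0.0))
        state = init_state(cfg, rng)
        c = cfg.box.length / 2.0
        R = cfg.mono_radius
        state.pos[0] = (c - R, c)
        state.pos[1] = (c + R, c)
        return state
    if name == "default_47":
        return init_state(SimConfig(), rng)
    if name == "crowded_200":
        return init_state(
            SimConfig(n_inert=200,
                      domains=DomainSpec(count=0, occupied_percent=0.0)),
            rng)
    if name == "two_domains":
        return init_state(
            SimConfig(domains=DomainSpec(count=2, occupied_percent=35.0,
                                         layout="uniform")),
            rng)
    raise ValueError(
        f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURE_NAMES)}"
    )
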