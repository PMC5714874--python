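"""Configuration files and trajectory I/O.

Configs are YAML mappings whose keys mirror :class:`SimulationConfig`
fields (plus a nested ``morphology`` block for Y-shaped receptors).
Unknown keys are rejected; all validation errors list the offending
keys.  Trajectories are written as plain CSV with a JSON metadata
sidecar (config echo, seed, time step, package version) so every output
is re-derivable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import (ConfigurationError, SimulationConfig, Trajectory,
                     compute_time_step)
from .geometry import YMorphology

__all__ = ["load_config", "config_to_dict", "save_trajectory",
           "load_trajectory"]

_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_MORPH_KEYS = {f.name for f in dataclasses.fields(YMorphology)}

_CSV_COLUMNS = ["time_s", "n_complex", "n_bound_ligands", "n_free_R",
                "n_free_L", "conc_complex_per_um3"]


def load_config(path) -> SimulationConfig:
    """Read and validate a simulation config from a YAML file.

    Missing keys take the documented defaults; unknown keys are an
    error (typos must not silently change an experiment).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {unknown}")
    kwargs = dict(raw)
    if "morphology" in kwargs and kwargs["morphology"] is not None:
        m = kwargs["morphology"]
        if not isinstance(m, dict):
            raise ConfigurationError("morphology must be a mapping")
        bad = sorted(set(m) - _MORPH_KEYS)
        if bad:
            raise ConfigurationError(f"unknown morphology keys: {bad}")
        kwargs["morphology"] = YMorphology(**m)
    config = SimulationConfig(**kwargs)
    compute_time_step(config)  # surfaces dt_override/probability errors now
    return config


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def save_trajectory(trajectory: Trajectory, csv_path,
                    version: str | None = None) -> None:
    """Write a trajectory CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    frame = trajectory.to_frame()
    frame.to_csv(csv_path, index=False, float_format="%.10g")
    meta = {
        "free_volume_um3": trajectory.free_volume,
        "stats": trajectory.stats,
        "version": version,
    }
    if trajectory.config is not None:
        meta["config"] = config_to_dict(trajectory.config)
        meta["seed"] = trajectory.config.seed
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_trajectory(csv_path) -> Trajectory:
    """Read a trajectory CSV written by :func:`save_trajectory` (or any
    CSV with at least ``time_s`` and ``conc_complex_per_um3``)."""
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    missing = [c for c in ("time_s",) if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"trajectory CSV lacks columns: {missing}")
    free_volume = np.nan
    meta_path = csv_path.with_suffix(".json")
    if meta_path.exists():
        with open(meta_path) as fh:
            free_volume = json.load(fh).get("free_volume_um3", np.nan)
    n = len(frame)
    get = lambda c: (frame[c].to_numpy() if c in frame.columns
                     else np.full(n, np.nan))
    n_complex = get("n_complex")
    if np.all(np.isnan(n_complex)) and "conc_complex_per_um3" in frame.columns:
        n_complex = frame["conc_complex_per_um3"].to_numpy() * free_volume
    return Trajectory(
        times=frame["time_s"].to_numpy(),
        n_complex=n_complex,
        n_bound_ligands=get("n_bound_ligands"),
        n_free_R=get("n_free_R"),
        n_free_L=get("n_free_L"),
        free_volume=float(free_volume),
    )
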