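"""Plain-text artifact writers: trajectory CSVs, metadata JSON, matrix dumps.

Every metadata file embeds the seed and a hash of the originating
configuration so that any two artifacts with equal hashes came from
identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gillespie import Trajectory
from .master import LatticeDistribution
from .model import ModelParams, SpectralSummary

__all__ = [
    "config_hash",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_events_csv",
    "write_metadata",
    "matrix_to_csv",
    "spectral_to_json",
    "distribution_to_csv",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(_jsonable(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_trajectory_csv(traj: Trajectory, path) -> Path:
    """Columns: t, n_0 .. n_{N-1}."""
    path = Path(path)
    cols = {"t": traj.sample_times}
    for i in range(traj.states.shape[1]):
        cols[f"n_{i}"] = traj.states[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_trajectory_csv(path, params: ModelParams, seed: int = -1) -> Trajectory:
    """Rebuild a (sample-level) trajectory from its CSV; no event log."""
    df = pd.read_csv(path)
    n_cols = [c for c in df.columns if c.startswith("n_")]
    states = df[n_cols].to_numpy(dtype=np.int64)
    return Trajectory(
        sample_times=df["t"].to_numpy(dtype=float),
        states=states,
        params=params,
        seed=seed,
        final_time=float(df["t"].iloc[-1]),
        final_state=states[-1],
    )


def write_events_csv(traj: Trajectory, path) -> Path:
    """Event log with columns: t, kind, node (needs ``record_events=True``)."""
    path = Path(path)
    if traj.events is None:
        raise ValueError("trajectory carries no event log (record_events=False)")
    pd.DataFrame(
        {
            "t": [e.t for e in traj.events],
            "kind": [e.kind for e in traj.events],
            "node": [e.node for e in traj.events],
        }
    ).to_csv(path, index=False)
    return path


def write_metadata(path, config: dict, **extras) -> Path:
    """Metadata JSON: the config, its hash, and any extra summary fields."""
    path = Path(path)
    payload = {
        "config": _jsonable(config),
        "config_hash": config_hash(config),
        **{k: _jsonable(v) for k, v in extras.items()},
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def matrix_to_csv(matrix: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.17g")
    return path


def spectral_to_json(summary: SpectralSummary, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    return path


def distribution_to_csv(dist: LatticeDistribution, path, threshold: float = 0.0) -> Path:
    """Columns: one per node population, plus the state probability."""
    path = Path(path)
    keep = dist.p >= threshold
    cols = {
        f"n_{i}": dist.space.states[keep, i] for i in range(dist.space.n_nodes)
    }
    cols["probability"] = dist.p[keep]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path
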