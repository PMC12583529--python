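"""Serialization of trajectories, sweeps and reports.

CSV numbers are pinned to 17 significant digits so repeated runs of the
same configuration produce byte-identical files; every artifact carries a
JSON sidecar (or embedded manifest) with the model name, full parameter
map, seed and solver settings needed to regenerate it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .integrate import Trajectory
from .params import ParameterSet

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_npz",
    "read_trajectory_npz",
    "write_sweep_csv",
    "write_json",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Write time plus state columns; metadata goes to ``<path>.json``."""
    path = Path(path)
    df = pd.DataFrame(traj.states, columns=list(traj.state_names))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    meta = {
        "model": traj.model_name,
        "params": traj.params.to_dict(),
        "seed": traj.seed,
        "state_names": list(traj.state_names),
        "competitive_pair": list(traj.competitive_pair),
        "transient_cutoff": int(traj.transient_cutoff),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory_csv` (requires the sidecar)."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(
        times=df["time"].to_numpy(),
        states=df[meta["state_names"]].to_numpy(),
        model_name=meta["model"],
        state_names=tuple(meta["state_names"]),
        competitive_pair=tuple(meta["competitive_pair"]),
        params=ParameterSet(meta["params"]),
        seed=int(meta["seed"]),
        transient_cutoff=int(meta["transient_cutoff"]),
    )


def write_trajectory_npz(traj: Trajectory, path: str | Path) -> Path:
    """Compressed binary container (exact float preservation) + sidecar."""
    path = Path(path)
    np.savez_compressed(path, times=traj.times, states=traj.states)
    meta = {
        "model": traj.model_name,
        "params": traj.params.to_dict(),
        "seed": traj.seed,
        "state_names": list(traj.state_names),
        "competitive_pair": list(traj.competitive_pair),
        "transient_cutoff": int(traj.transient_cutoff),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_trajectory_npz(path: str | Path) -> Trajectory:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    with np.load(path) as data:
        times, states = data["times"], data["states"]
    return Trajectory(
        times=times,
        states=states,
        model_name=meta["model"],
        state_names=tuple(meta["state_names"]),
        competitive_pair=tuple(meta["competitive_pair"]),
        params=ParameterSet(meta["params"]),
        seed=int(meta["seed"]),
        transient_cutoff=int(meta["transient_cutoff"]),
    )


def write_sweep_csv(sweep, path: str | Path) -> Path:
    """Tidy per-point feature table of a sweep result."""
    path = Path(path)
    sweep.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path
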