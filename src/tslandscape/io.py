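"""Serialization: trajectories/ensembles to HDF5 and CSV, schema version 1."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from tslandscape.simulate import Ensemble, ParameterSchedule, Trajectory

SCHEMA_VERSION = 1

__all__ = [
    "SCHEMA_VERSION",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "ensemble_to_hdf5",
    "ensemble_from_hdf5",
    "path_to_csv",
    "write_json",
    "config_hash",
]


def _schedule_to_dict(schedule):
    if schedule is None:
        return None
    return {
        "name": schedule.name, "mode": schedule.mode, "start": schedule.start,
        "end": schedule.end, "duration": schedule.duration,
    }


def _schedule_from_dict(d):
    if d is None:
        return None
    return ParameterSchedule(**d)


def trajectory_to_csv(traj: Trajectory, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(traj.states, columns=list(traj.labels))
    df.insert(0, "time", traj.times)
    header = {
        "schema": SCHEMA_VERSION, "model_id": traj.model_id, "seed": traj.seed,
        "schedule": _schedule_to_dict(traj.schedule),
    }
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        df.to_csv(fh, index=False)
    return path


def trajectory_from_csv(path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        header = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    labels = tuple(c for c in df.columns if c != "time")
    return Trajectory(
        times=df["time"].to_numpy(), states=df[list(labels)].to_numpy(),
        labels=labels, model_id=header.get("model_id", "unknown"),
        seed=int(header.get("seed", 0)),
        schedule=_schedule_from_dict(header.get("schedule")),
    )


def ensemble_to_hdf5(ens: Ensemble, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=ens.times)
        fh.create_dataset("states", data=ens.states, compression="gzip")
        fh.create_dataset("member_seeds", data=ens.member_seeds)
        fh.attrs["schema"] = SCHEMA_VERSION
        fh.attrs["model_id"] = ens.model_id
        fh.attrs["base_seed"] = ens.base_seed
        fh.attrs["labels"] = json.dumps(list(ens.labels))
        fh.attrs["schedule"] = json.dumps(_schedule_to_dict(ens.schedule))
    return path


def ensemble_from_hdf5(path) -> Ensemble:
    with h5py.File(path, "r") as fh:
        return Ensemble(
            times=fh["times"][:], states=fh["states"][:],
            member_seeds=fh["member_seeds"][:],
            labels=tuple(json.loads(fh.attrs["labels"])),
            model_id=str(fh.attrs["model_id"]),
            base_seed=int(fh.attrs["base_seed"]),
            schedule=_schedule_from_dict(json.loads(fh.attrs["schedule"])),
        )


def path_to_csv(path_obj, out_path, extra_header: dict | None = None) -> Path:
    """Transition path as CSV: arc-length coordinate plus per-species columns."""
    out_path = Path(out_path)
    df = pd.DataFrame(path_obj.states, columns=list(path_obj.labels))
    df.insert(0, "arclength", path_obj.arclength())
    header = {"schema": SCHEMA_VERSION, "duration": path_obj.duration}
    header.update(extra_header or {})
    with open(out_path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        df.to_csv(fh, index=False)
    return out_path


def write_json(obj, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
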