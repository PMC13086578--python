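"""Persistence: trajectories to HDF5, metrics to CSV, stacks to TIFF."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import FieldState, ModelParams
from .solver import Trajectory, build_geometry

__all__ = ["save_trajectory", "load_trajectory", "save_metrics",
           "write_stack_tiff", "read_stack_tiff"]


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to HDF5: per-snapshot phi_s/phi_ns datasets,
    params/geometry/schedule as JSON attributes, metrics as a table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["params"] = json.dumps(traj.params.to_dict())
        f.attrs["geometry"] = json.dumps(traj.geometry.to_dict())
        f.attrs["schedule"] = traj.schedule_description
        f.attrs["rng_seed"] = -1 if traj.rng_seed is None else traj.rng_seed
        grp = f.create_group("snapshots")
        for i, s in enumerate(traj.snapshots):
            g = grp.create_group(f"{i:05d}")
            g.create_dataset("phi_s", data=s.phi_s, compression="gzip")
            g.create_dataset("phi_ns", data=s.phi_ns, compression="gzip")
            g.attrs["time"] = s.time
            g.attrs["grid_spacing"] = s.grid_spacing
        mg = f.create_group("metrics")
        for col in traj.metrics.columns:
            vals = traj.metrics[col].to_numpy()
            if vals.dtype == object:
                continue  # nested lists (centroids) live in the CSV export
            mg.create_dataset(col, data=vals)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        params = ModelParams.from_dict(json.loads(f.attrs["params"]))
        geometry = build_geometry(json.loads(f.attrs["geometry"]))
        snaps = []
        for key in sorted(f["snapshots"].keys()):
            g = f["snapshots"][key]
            snaps.append(FieldState(
                g["phi_s"][...], g["phi_ns"][...],
                float(g.attrs["time"]), float(g.attrs["grid_spacing"]),
            ))
        metrics = pd.DataFrame(
            {col: f["metrics"][col][...] for col in f["metrics"].keys()}
        )
        seed = int(f.attrs["rng_seed"])
        return Trajectory(
            snapshots=snaps, metrics=metrics, params=params,
            geometry=geometry, schedule_description=str(f.attrs["schedule"]),
            rng_seed=None if seed < 0 else seed,
        )


def save_metrics(metrics: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(path, index=False)


def write_stack_tiff(stack: np.ndarray, path) -> None:
    """Write one (channel, z, y, x) stack as a TIFF file."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     metadata={"axes": "CZYX"})


def read_stack_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
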