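"""Trajectory persistence: HDF5 snapshots plus a light CSV summary."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import FieldState, ModelParameters, free_energy
from .simulate import InitialConditionSpec, Trajectory

__all__ = ["save_trajectory", "load_trajectory", "trajectory_summary"]


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """One HDF5 group per recorded second with the five field datasets;
    parameters, initial-condition spec and scheme metadata as attributes."""
    with h5py.File(path, "w") as fh:
        for key, val in traj.params.as_dict().items():
            fh.attrs[f"param_{key}"] = val
        if traj.ic is not None:
            fh.attrs["ic_ratio"] = traj.ic.ratio
            fh.attrs["ic_P0"] = traj.ic.P0
            fh.attrs["ic_noise_amplitude"] = traj.ic.noise_amplitude
            fh.attrs["ic_seed"] = traj.ic.seed
        fh.attrs["t_cap"] = traj.t_cap
        for key, val in traj.meta.items():
            if isinstance(val, (int, float, str)):
                fh.attrs[f"meta_{key}"] = val
        for snap in traj.snapshots:
            grp = fh.create_group(f"t_{int(round(snap.time)):06d}")
            grp.attrs["time"] = snap.time
            grp.attrs["h"] = snap.h
            for name, arr in snap.fields().items():
                grp.create_dataset(name, data=arr, compression="gzip")


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        params = ModelParameters(**{
            k.removeprefix("param_"): float(v)
            for k, v in fh.attrs.items() if k.startswith("param_")})
        ic = None
        if "ic_ratio" in fh.attrs:
            ic = InitialConditionSpec(
                ratio=str(fh.attrs["ic_ratio"]),
                P0=float(fh.attrs["ic_P0"]),
                noise_amplitude=float(fh.attrs["ic_noise_amplitude"]),
                seed=int(fh.attrs["ic_seed"]))
        snapshots = []
        for key in sorted(k for k in fh if k.startswith("t_")):
            grp = fh[key]
            snapshots.append(FieldState(
                K1=grp["K1"][...], K2=grp["K2"][...], P=grp["P"][...],
                R1=grp["R1"][...], R2=grp["R2"][...],
                h=float(grp.attrs["h"]), time=float(grp.attrs["time"])))
        meta = {k.removeprefix("meta_"): fh.attrs[k]
                for k in fh.attrs if k.startswith("meta_")}
        return Trajectory(snapshots, params, ic,
                          t_cap=float(fh.attrs["t_cap"]), meta=meta)


def trajectory_summary(traj: Trajectory) -> pd.DataFrame:
    """Per-second means, max total complex and free energy."""
    rows = []
    for snap in traj.snapshots:
        rows.append({
            "time": snap.time,
            "mean_K1": float(snap.K1.mean()),
            "mean_K2": float(snap.K2.mean()),
            "mean_P": float(snap.P.mean()),
            "max_K1_plus_K2": float((snap.K1 + snap.K2).max()),
            "free_energy": free_energy(snap, traj.params),
        })
    return pd.DataFrame(rows)
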