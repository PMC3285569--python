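"""Readers and writers for run artifacts.

Tabular outputs (APD/DI tables, restitution curves, episode summaries) are
CSV with ``#``-prefixed header comments carrying provenance (config hash,
package version). Array outputs (field snapshots, domain masks, cell-state
snapshots) are HDF5 containers of named arrays with scalar metadata
attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .geometry import TissueDomain
from .measure import RestitutionCurve
from .solver import FieldState, Recordings

__all__ = [
    "write_table", "read_table",
    "write_curve", "read_curve",
    "save_snapshots", "load_snapshots",
    "save_state", "load_state",
    "save_domain", "load_domain",
]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# atriasim {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_curve(curve: RestitutionCurve, path, meta: dict | None = None) -> None:
    df = pd.DataFrame({"di_ms": curve.di, "cv_cm_per_ms": curve.cv,
                       "apd_ms": curve.apd})
    if curve.cycle_lengths.size == len(df):
        df["cycle_length_ms"] = curve.cycle_lengths
    write_table(df, path, {**(meta or {}), **curve.meta})


def read_curve(path) -> RestitutionCurve:
    df = read_table(path)
    cl = (df["cycle_length_ms"].to_numpy()
          if "cycle_length_ms" in df else np.empty(0))
    return RestitutionCurve(di=df["di_ms"].to_numpy(),
                            cv=df["cv_cm_per_ms"].to_numpy(),
                            apd=df["apd_ms"].to_numpy(), cycle_lengths=cl)


def save_snapshots(rec: Recordings, path, dx: float | None = None,
                   meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("snapshot_times", data=rec.snapshot_times)
        f.create_dataset("snapshots", data=rec.snapshots)
        f.create_dataset("trace_times", data=rec.times)
        f.create_dataset("traces", data=rec.traces)
        f.create_dataset("sites", data=rec.sites)
        f.attrs["version"] = __version__
        if dx is not None:
            f.attrs["dx_cm"] = dx
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_snapshots(path) -> Recordings:
    with h5py.File(path, "r") as f:
        return Recordings(times=f["trace_times"][()], traces=f["traces"][()],
                          sites=f["sites"][()],
                          snapshot_times=f["snapshot_times"][()],
                          snapshots=f["snapshots"][()])


def save_state(state: FieldState, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("states", data=state.states)
        f.attrs["t_ms"] = state.t
        f.attrs["version"] = __version__


def load_state(path) -> FieldState:
    with h5py.File(path, "r") as f:
        return FieldState(states=f["states"][()], t=float(f.attrs["t_ms"]))


def save_domain(domain: TissueDomain, path) -> None:
    """Arrays to HDF5; manifest (seed, config, obstacles) as a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("active", data=domain.active)
        f.create_dataset("labels", data=domain.labels)
        f.create_dataset("D", data=domain.D)
        f.attrs["dx_cm"] = domain.dx
        f.attrs["structural_scale"] = domain.structural_scale
        f.attrs["version"] = __version__
    side = {"seed": domain.seed, "manifest": domain.manifest,
            "obstacles": domain.obstacles, "shape": list(domain.shape)}
    Path(str(path) + ".manifest.json").write_text(json.dumps(side, indent=1, default=str))


def load_domain(path) -> TissueDomain:
    with h5py.File(path, "r") as f:
        active = f["active"][()].astype(bool)
        labels = f["labels"][()]
        D = f["D"][()]
        dx = float(f.attrs["dx_cm"])
        s = float(f.attrs["structural_scale"])
    side_path = Path(str(path) + ".manifest.json")
    side = json.loads(side_path.read_text()) if side_path.exists() else {}
    return TissueDomain(shape=tuple(active.shape), dx=dx, active=active,
                        labels=labels, D=D, structural_scale=s,
                        seed=side.get("seed"), manifest=side.get("manifest", {}),
                        obstacles=side.get("obstacles", []))
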