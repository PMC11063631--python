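"""HDF5/CSV persistence for sessions and derived results.

A session is stored as ``<name>.h5`` (datasets ``dff`` [neurons × frames,
float32], ``frame_hz``, ``run_bounds``) plus sibling ``<name>.events.csv``
and ``<name>.covariates.csv`` tables.  Binned sessions, embeddings and
cluster labels are written into a single HDF5 analysis file.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import BinnedSession, Session


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_suffix("").with_suffix(f".{suffix}.csv")


def save_session(session: Session, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=session.dff.astype(np.float32))
        f.attrs["frame_hz"] = session.frame_hz
        f.attrs["microscope_id"] = session.microscope_id
        f.attrs["reward_type"] = session.reward_type
        f.create_dataset("run_bounds", data=np.asarray(session.run_bounds))
    session.events.to_csv(_sidecar(path, "events"), index=False)
    session.covariates.to_csv(_sidecar(path, "covariates"), index=False)


def load_session(path: str | Path) -> Session:
    path = Path(path)
    with h5py.File(path, "r") as f:
        dff = f["dff"][()]
        frame_hz = float(f.attrs["frame_hz"])
        microscope_id = str(f.attrs.get("microscope_id", "A"))
        reward_type = str(f.attrs.get("reward_type", "water"))
        run_bounds = [tuple(map(int, rb)) for rb in f["run_bounds"][()]]
    events = pd.read_csv(_sidecar(path, "events"), keep_default_na=False)
    if "responded" in events.columns:
        events["responded"] = events["responded"].astype(bool)
    covariates = pd.read_csv(_sidecar(path, "covariates"))
    return Session(
        dff=dff,
        frame_hz=frame_hz,
        run_bounds=run_bounds,
        events=events,
        covariates=covariates,
        microscope_id=microscope_id,
        reward_type=reward_type,
    )


def save_binned(binned: BinnedSession, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=binned.z)
        f.attrs["bin_s"] = binned.bin_s
        f.attrs["per_run_zscore"] = binned.per_run_zscore
        f.attrs["frame_hz"] = binned.frame_hz
        f.attrs["reward_type"] = binned.reward_type
        f.create_dataset("kept_neurons", data=binned.kept_neurons)
        f.create_dataset("run_bin_bounds", data=np.asarray(binned.run_bin_bounds))
    binned.bin_events.to_csv(_sidecar(path, "events"), index=False)
    binned.covariates.to_csv(_sidecar(path, "covariates"), index=False)


def load_binned(path: str | Path) -> BinnedSession:
    path = Path(path)
    with h5py.File(path, "r") as f:
        z = f["z"][()]
        bin_s = float(f.attrs["bin_s"])
        per_run = bool(f.attrs["per_run_zscore"])
        frame_hz = float(f.attrs["frame_hz"])
        reward_type = str(f.attrs.get("reward_type", "water"))
        kept = f["kept_neurons"][()]
        bounds = [tuple(map(int, rb)) for rb in f["run_bin_bounds"][()]]
    events = pd.read_csv(_sidecar(path, "events"), keep_default_na=False)
    if "responded" in events.columns:
        events["responded"] = events["responded"].astype(bool)
    covariates = pd.read_csv(_sidecar(path, "covariates"))
    return BinnedSession(
        z=z,
        bin_s=bin_s,
        kept_neurons=kept,
        bin_events=events,
        covariates=covariates,
        run_bin_bounds=bounds,
        per_run_zscore=per_run,
        frame_hz=frame_hz,
        reward_type=reward_type,
    )


def save_array(arr: np.ndarray, path: str | Path, name: str = "data") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(name, data=arr)


def load_array(path: str | Path, name: str = "data") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[name][()]
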