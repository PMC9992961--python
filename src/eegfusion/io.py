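"""Readers/writers for the epoched-EEG containers.

Two dialects: a single HDF5 file (datasets /data, /labels; attrs fs,
channel_names, class_names) and a plain-text directory (one whitespace
matrix per trial plus labels.csv).
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .data import EEGEpochSet

__all__ = ["save_epochs_hdf5", "load_epochs_hdf5",
           "save_epochs_dir", "load_epochs_dir", "load_epochs"]


def save_epochs_hdf5(epochs: EEGEpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["fs"] = epochs.fs
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        f.attrs["class_names"] = [str(c) for c in epochs.class_names]


def load_epochs_hdf5(path) -> EEGEpochSet:
    with h5py.File(path, "r") as f:
        return EEGEpochSet(
            f["data"][...],
            f["labels"][...],
            float(f.attrs["fs"]),
            [str(c) for c in f.attrs["channel_names"]],
            [str(c) for c in f.attrs["class_names"]],
        )


def save_epochs_dir(epochs: EEGEpochSet, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = len(str(epochs.n_trials - 1))
    with open(path / "labels.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["trial_id", "label"])
        for i, lab in enumerate(epochs.labels):
            w.writerow([f"trial{i:0{width}d}", int(lab)])
    with open(path / "meta.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["fs", epochs.fs])
        w.writerow(["channel_names", *epochs.channel_names])
        w.writerow(["class_names", *epochs.class_names])
    for i in range(epochs.n_trials):
        np.savetxt(path / f"trial{i:0{width}d}.txt", epochs.data[i])


def load_epochs_dir(path) -> EEGEpochSet:
    path = Path(path)
    with open(path / "labels.csv", newline="") as f:
        rows = list(csv.reader(f))[1:]
    trial_ids = [r[0] for r in rows]
    labels = np.array([int(r[1]) for r in rows])
    with open(path / "meta.csv", newline="") as f:
        meta = {r[0]: r[1:] for r in csv.reader(f)}
    data = np.stack([np.loadtxt(path / f"{tid}.txt", ndmin=2)
                     for tid in trial_ids])
    return EEGEpochSet(data, labels, float(meta["fs"][0]),
                       meta["channel_names"], meta["class_names"])


def load_epochs(path) -> EEGEpochSet:
    """Dispatch on path type: directory dialect or HDF5 file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such epoch container: {path}")
    if path.is_dir():
        return load_epochs_dir(path)
    return load_epochs_hdf5(path)
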