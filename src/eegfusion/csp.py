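"""Common spatial patterns with a one-vs-rest multiclass extension.

The projection ``Z = W @ E`` maps a channels x samples trial onto
"virtual channels" ordered so the first rows carry maximal variance for
the positive class and the last rows maximal variance for the rest.  W is
obtained from the generalized eigenproblem of (C+, C+ + C-) on trial-
averaged, trace-normalized covariances with a small shrinkage term.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import linalg

from .data import EEGEpochSet

__all__ = ["CSPModel", "fit_csp", "fit_csp_ovr", "project",
           "extract_virtual_channels", "class_covariance"]


@dataclass
class CSPModel:
    """Spatial filter bank for one binary (or one-vs-rest) problem.

    W rows are filters sorted by descending generalized eigenvalue of the
    positive class; ``eigenvalues[j]`` is the fraction of (normalized)
    variance filter j captures from the positive class, in (0, 1).
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    positive_class: int
    trace_normalized: bool = True

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.attrs["positive_class"] = int(self.positive_class)
            f.attrs["trace_normalized"] = bool(self.trace_normalized)

    @classmethod
    def load_hdf5(cls, path) -> "CSPModel":
        with h5py.File(path, "r") as f:
            return cls(f["W"][...], f["eigenvalues"][...],
                       int(f.attrs["positive_class"]),
                       bool(f.attrs["trace_normalized"]))


def class_covariance(trials: np.ndarray, shrinkage: float = 1e-6) -> np.ndarray:
    """Average of per-trial trace-normalized covariances, with shrinkage
    toward a scaled identity to guarantee positive definiteness."""
    if trials.ndim != 3 or trials.shape[0] < 2:
        raise ValueError("need >= 2 trials of shape channels x samples")
    m = trials.shape[1]
    cov = np.zeros((m, m))
    for e in trials:
        c = e @ e.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("zero-variance trial; cannot normalize covariance")
        cov += c / tr
    cov /= trials.shape[0]
    return (1.0 - shrinkage) * cov + shrinkage * (np.trace(cov) / m) * np.eye(m)


def fit_csp(epochs: EEGEpochSet, positive_class: int,
            shrinkage: float = 1e-6) -> CSPModel:
    """Fit one binary CSP problem: ``positive_class`` vs all other labels."""
    pos = epochs.data[epochs.labels == positive_class]
    neg = epochs.data[epochs.labels != positive_class]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"need >= 2 trials per side (got {len(pos)} positive, {len(neg)} rest)")
    if epochs.n_channels < 2:
        raise ValueError("CSP needs at least 2 channels")
    c_pos = class_covariance(pos, shrinkage)
    c_neg = class_covariance(neg, shrinkage)
    try:
        evals, evecs = linalg.eigh(c_pos, c_pos + c_neg)
    except linalg.LinAlgError as exc:  # pragma: no cover - shrinkage guards this
        raise ValueError(f"covariance rank-deficient beyond repair: {exc}") from exc
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    W = evecs[:, order].T
    # sign convention: largest-magnitude coefficient of each filter positive
    signs = np.sign(W[np.arange(len(W)), np.abs(W).argmax(axis=1)])
    W = W * signs[:, None]
    return CSPModel(W=W, eigenvalues=evals, positive_class=int(positive_class))


def fit_csp_ovr(epochs: EEGEpochSet, shrinkage: float = 1e-6) -> list[CSPModel]:
    """One model per class for >= 3 classes; a single model for 2 classes."""
    classes = np.unique(epochs.labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    for k in classes:
        if (epochs.labels == k).sum() < 2:
            raise ValueError(f"class {k} has fewer than 2 trials")
    if len(classes) == 2:
        return [fit_csp(epochs, int(classes[0]), shrinkage)]
    return [fit_csp(epochs, int(k), shrinkage) for k in classes]


def project(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Z = W @ E."""
    trial = np.asarray(trial)
    if trial.ndim != 2 or trial.shape[0] != model.n_channels:
        raise ValueError(
            f"trial shape {trial.shape} incompatible with {model.n_channels}-channel model")
    return model.W @ trial


def extract_virtual_channels(models: list[CSPModel], epochs: EEGEpochSet,
                             m: int = 1) -> np.ndarray:
    """First m and last m rows of Z per model, concatenated across models.

    Returns trials x (2m * n_models) x samples.
    """
    if not models:
        raise ValueError("need at least one CSP model")
    M = models[0].n_channels
    if 2 * m >= M:
        raise ValueError(f"2m = {2 * m} must be < number of channels {M}")
    rows = list(range(m)) + list(range(M - m, M))
    out = np.empty((epochs.n_trials, 2 * m * len(models), epochs.n_samples))
    for i in range(epochs.n_trials):
        parts = [project(model, epochs.data[i])[rows] for model in models]
        out[i] = np.concatenate(parts, axis=0)
    return out
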