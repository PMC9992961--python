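"""Epoched EEG container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGEpochSet", "SENSORIMOTOR_CHANNELS"]

#: Default 20-channel sensorimotor montage.
SENSORIMOTOR_CHANNELS = (
    "FC1", "FC2", "FC3", "FC4", "FC5", "FC6",
    "C1", "C2", "C3", "C4", "C5", "C6",
    "CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
    "CZ", "CPZ",
)


@dataclass
class EEGEpochSet:
    """Trials x channels x samples EEG (microvolts) with integer labels.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    labels : ndarray of int, shape (n_trials,)
        Class indices in ``[0, n_classes)``.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    class_names : list of str
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length does not match trial count")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel dim")
        if not self.class_names:
            self.class_names = [f"class{k}" for k in range(self.n_classes)]
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels outside [0, n_classes)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else int(self.labels.max()) + 1

    def subset(self, idx) -> "EEGEpochSet":
        idx = np.asarray(idx)
        return EEGEpochSet(self.data[idx], self.labels[idx], self.fs,
                          list(self.channel_names), list(self.class_names))

    def copy_with(self, data=None, fs=None, channel_names=None) -> "EEGEpochSet":
        return EEGEpochSet(
            self.data if data is None else data,
            self.labels,
            self.fs if fs is None else fs,
            list(self.channel_names) if channel_names is None else list(channel_names),
            list(self.class_names),
        )
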