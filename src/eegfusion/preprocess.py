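"""Signal conditioning: channel selection, band-pass, decimation, windowing.

Default pipeline reproduces the 20-channel / 8-30 Hz / 250 Hz / 4 s
configuration, so a >=4 s trial at any integer multiple of 250 Hz ends up
as a 20 x 1000 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import EEGEpochSet, SENSORIMOTOR_CHANNELS

__all__ = ["PreprocConfig", "select_channels", "bandpass", "downsample",
           "window_epochs", "preprocess"]


@dataclass
class PreprocConfig:
    channels: tuple[str, ...] = SENSORIMOTOR_CHANNELS
    band: tuple[float, float] = (8.0, 30.0)
    target_fs: float = 250.0
    t_start: float = 0.0
    duration: float = 4.0
    filter_order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        lo, hi = self.band
        if not lo < hi:
            raise ValueError(f"band low {lo} must be < high {hi}")
        if hi >= self.target_fs / 2:
            raise ValueError(
                f"band high {hi} must be below target Nyquist {self.target_fs / 2}")
        n = self.duration * self.target_fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * target_fs must be an integer")


def select_channels(epochs: EEGEpochSet, names) -> EEGEpochSet:
    """Reorder/subset the channel dimension to ``names`` exactly."""
    lookup = {name: i for i, name in enumerate(epochs.channel_names)}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise KeyError(f"channels not present: {missing}")
    idx = [lookup[n] for n in names]
    return epochs.copy_with(data=epochs.data[:, idx, :],
                            channel_names=list(names))


def _sos(band, fs, order):
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band high {hi} at or above Nyquist {fs / 2}")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(epochs: EEGEpochSet, config: PreprocConfig) -> EEGEpochSet:
    """Per-channel Butterworth band-pass; zero-phase (forward-backward) by
    default, with odd-reflection padding against edge transients."""
    sos = _sos(config.band, epochs.fs, config.filter_order)
    if config.zero_phase:
        out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        out = signal.sosfilt(sos, epochs.data, axis=-1)
    return epochs.copy_with(data=np.ascontiguousarray(out))


def downsample(epochs: EEGEpochSet, target_fs: float) -> EEGEpochSet:
    """Integer-factor decimation by sample picking.

    Callers must band-limit first (the 8-30 Hz band-pass keeps content far
    below the 125 Hz target Nyquist, so no extra anti-alias stage is
    applied here).
    """
    ratio = epochs.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fs {epochs.fs} is not an integer multiple of target {target_fs}")
    q = int(round(ratio))
    if q == 1:
        return epochs
    return epochs.copy_with(data=epochs.data[:, :, ::q], fs=target_fs)


def window_epochs(epochs: EEGEpochSet, t_start: float,
                  duration: float) -> EEGEpochSet:
    """Half-open window [t_start, t_start + duration) in samples."""
    i0 = int(round(t_start * epochs.fs))
    n = int(round(duration * epochs.fs))
    if i0 < 0 or i0 + n > epochs.n_samples:
        raise ValueError(
            f"window [{t_start}, {t_start + duration}) s exceeds trial extent "
            f"of {epochs.n_samples / epochs.fs} s")
    return epochs.copy_with(data=epochs.data[:, :, i0:i0 + n])


def preprocess(epochs: EEGEpochSet, config: PreprocConfig | None = None) -> EEGEpochSet:
    """select -> band-pass -> decimate -> window composition."""
    config = config or PreprocConfig()
    names = [c for c in config.channels if c in epochs.channel_names]
    if len(names) == len(config.channels):
        epochs = select_channels(epochs, config.channels)
    # else: keep all channels (synthetic montages may not carry real labels)
    epochs = bandpass(epochs, config)
    epochs = downsample(epochs, config.target_fs)
    return window_epochs(epochs, config.t_start, config.duration)
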