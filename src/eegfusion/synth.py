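"""Synthetic motor-imagery EEG with class-specific band-power attenuation.

Each class is associated with one band-limited oscillatory source.  Every
trial carries all sources mixed through a fixed orthonormal spatial matrix
on top of 1/f background noise; in trials of class ``k`` the amplitude of
source ``k`` is scaled by ``(1 - erd_depth)``, mimicking event-related
desynchronization.  The mixing matrix is drawn once per dataset from the
seed, so spatial structure is recoverable and known to tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data import EEGEpochSet, SENSORIMOTOR_CHANNELS

__all__ = ["SynthConfig", "generate_mi_dataset", "band_power", "mixing_matrix"]


@dataclass
class SynthConfig:
    n_classes: int = 2
    n_trials_per_class: int = 50
    n_channels: int = 20
    fs: float = 250.0
    duration: float = 4.0
    source_freq_band: tuple[float, float] = (10.0, 22.0)
    erd_depth: float = 0.5
    noise_exponent: float = 1.0
    snr: float = 1.0
    seed: int = 0
    distinct_subbands: bool = True
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must be in [0, 1)")
        lo, hi = self.source_freq_band
        if lo >= hi:
            raise ValueError(f"invalid band: low {lo} >= high {hi}")
        if hi > self.fs / 2:
            raise ValueError(f"band high {hi} exceeds Nyquist {self.fs / 2}")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        if self.n_channels < self.n_classes:
            raise ValueError("need at least one channel per class source")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def source_band(self, k: int) -> tuple[float, float]:
        """Frequency band of source ``k``.

        With ``distinct_subbands`` (default) the configured band is split
        into one contiguous sub-band per class, mimicking rhythm-specific
        desynchronization (e.g. mu vs beta); otherwise all sources share
        the full band.
        """
        lo, hi = self.source_freq_band
        if not self.distinct_subbands:
            return lo, hi
        width = (hi - lo) / self.n_classes
        return lo + k * width, lo + (k + 1) * width


def mixing_matrix(config: SynthConfig) -> np.ndarray:
    """Orthonormal channels x classes source-mixing matrix for ``config``.

    Columns are a QR-orthonormalization of identity columns plus a small
    seeded jitter, so source ``k`` stays dominant on channel ``k`` — that
    gives tests a known "dominant channel" and CSP a recoverable filter.
    """
    rng = np.random.default_rng([config.seed, 101])
    a = np.zeros((config.n_channels, config.n_classes))
    a[:config.n_classes, :] = np.eye(config.n_classes)
    a += 0.2 * rng.standard_normal(a.shape)
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix sign so diagonal weights are positive
    return q


def _pink_noise(rng: np.random.Generator, shape: tuple, exponent: float,
                fs: float) -> np.ndarray:
    """Gaussian noise shaped to a 1/f^exponent amplitude spectrum, unit RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n, axis=-1)
    rms = shaped.std(axis=-1, keepdims=True)
    return shaped / np.maximum(rms, 1e-30)


def _oscillatory_source(rng: np.random.Generator, n_samples: int, fs: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Band-limited unit-RMS oscillation (random phases within the band)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec = np.zeros(len(freqs), dtype=complex)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    k = int(mask.sum())
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    src = np.fft.irfft(spec, n=n_samples)
    return src / max(src.std(), 1e-30)


def generate_mi_dataset(config: SynthConfig) -> EEGEpochSet:
    """Generate a seeded, ERD-structured epoched dataset.

    Returns ``n_classes * n_trials_per_class`` trials in class-blocked
    order (labels 0,0,...,1,1,...).  Identical configs (including seed)
    produce bit-identical output.
    """
    rng = np.random.default_rng([config.seed, 202])
    mix = mixing_matrix(config)  # separate stream keyed on the same seed
    n = config.n_samples
    n_trials = config.n_classes * config.n_trials_per_class

    data = np.empty((n_trials, config.n_channels, n), dtype=np.float64)
    labels = np.empty(n_trials, dtype=np.int64)
    t = 0
    for k in range(config.n_classes):
        for _ in range(config.n_trials_per_class):
            amps = np.ones(config.n_classes)
            amps[k] = 1.0 - config.erd_depth
            sources = np.stack([
                amp * _oscillatory_source(rng, n, config.fs,
                                          config.source_band(j))
                for j, amp in enumerate(amps)
            ])
            trial = config.snr * (mix @ sources)
            noise = _pink_noise(rng, (config.n_channels, n),
                                config.noise_exponent, config.fs)
            common = _pink_noise(rng, (n,), config.noise_exponent, config.fs)
            trial += noise + 0.1 * common[None, :]
            data[t] = trial
            labels[t] = k
            t += 1

    if config.class_names:
        class_names = list(config.class_names)
    else:
        class_names = [f"class{k}" for k in range(config.n_classes)]
    if config.n_channels == len(SENSORIMOTOR_CHANNELS):
        channels = list(SENSORIMOTOR_CHANNELS)
    else:
        channels = [f"CH{i}" for i in range(config.n_channels)]
    return EEGEpochSet(data, labels, config.fs, channels, class_names)


def band_power(trial: np.ndarray, fs: float, band: tuple[float, float],
               channel: int) -> float:
    """Integrated periodogram power (signal units squared) over ``band``.

    Serves as the independent band-power oracle for the generator's ERD
    contract; a pure unit sinusoid inside the band integrates to ~0.5.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, {fs / 2})")
    x = np.asarray(trial)[channel]
    freqs, psd = signal.periodogram(x, fs=fs, window="boxcar",
                                    detrend=False, scaling="density")
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    df = freqs[1] - freqs[0]
    return float(psd[mask].sum() * df)
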