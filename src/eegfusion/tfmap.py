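"""Morlet scalograms of CSP virtual channels rendered as 64x64 RGB images.

The wavelet is the L2-normalized complex Morlet (Gaussian-windowed complex
exponential, center parameter omega0).  Coefficients are computed by FFT
convolution with reflect padding of half the wavelet support, magnitude
maps are binned in time, combined across virtual channels, min-max
normalized per trial, bilinearly resized and passed through a fixed
jet-style lookup table — the data path has no plotting dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from skimage.transform import resize as _resize

from .csp import CSPModel, project
from .data import EEGEpochSet

__all__ = ["CWTConfig", "TFImage", "morlet_cwt", "scalogram", "render_image",
           "trial_to_image", "epochs_to_images", "jet_lut"]


def _default_freqs() -> np.ndarray:
    return np.linspace(8.0, 30.0, 64)


@dataclass
class CWTConfig:
    freqs: np.ndarray = field(default_factory=_default_freqs)
    omega0: float = 6.0
    time_bins: int = 64
    image_size: int = 64
    image_mode: str = "mean_colormap"  # or "ovr_planes"
    magnitude_power: float = 1.0  # 2.0 -> power scalograms

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or len(self.freqs) < 1:
            raise ValueError("freqs must be a 1-D list of center frequencies")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.time_bins < 1:
            raise ValueError("time_bins must be >= 1")
        if self.image_mode not in ("mean_colormap", "ovr_planes"):
            raise ValueError(f"unknown image_mode {self.image_mode!r}")


@dataclass
class TFImage:
    pixels: np.ndarray  # 64 x 64 x 3 floats in [0, 1]
    trial_id: int = -1
    label: int = -1

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixels")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixels outside [0, 1]")

    def save_png(self, path) -> None:
        """8-bit RGB export."""
        from PIL import Image
        arr = np.clip(self.pixels * 255.0, 0, 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(path)


def jet_lut(n: int = 256) -> np.ndarray:
    """Classic piecewise-linear blue->cyan->yellow->red table, n x 3."""
    x = np.linspace(0.0, 1.0, n)
    r = np.clip(1.5 - np.abs(4 * x - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * x - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * x - 1), 0, 1)
    return np.stack([r, g, b], axis=1)


_JET = jet_lut()


def _morlet_kernel(freq: float, fs: float, omega0: float) -> np.ndarray:
    """Discrete L2-normalized complex Morlet at center frequency ``freq``."""
    sigma_t = omega0 / (2 * np.pi * freq)  # seconds
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    wav -= wav.mean()  # zero-mean correction (negligible for omega0 >= 5)
    return wav / np.linalg.norm(wav)


def morlet_cwt(x: np.ndarray, fs: float, config: CWTConfig) -> np.ndarray:
    """Complex coefficient matrix, rows = config.freqs, columns = time.

    Reflect padding of half the wavelet support suppresses edge ramps.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if np.any(config.freqs <= 0) or np.any(config.freqs >= fs / 2):
        raise ValueError(f"freqs must lie inside (0, {fs / 2})")
    n = len(x)
    out = np.empty((len(config.freqs), n), dtype=complex)
    for i, f in enumerate(config.freqs):
        wav = _morlet_kernel(f, fs, config.omega0)
        half = len(wav) // 2
        pad = min(half, n - 1)
        xp = np.pad(x, pad, mode="reflect")
        conv = _sig.fftconvolve(xp, wav, mode="same")
        out[i] = conv[pad:pad + n]
    return out


def scalogram(coefs: np.ndarray, time_bins: int) -> np.ndarray:
    """|coefs| averaged over ``time_bins`` near-equal contiguous segments.

    Segment lengths differ by at most one sample; every sample is used
    exactly once.
    """
    coefs = np.asarray(coefs)
    n = coefs.shape[1]
    if time_bins > n:
        raise ValueError(f"time_bins {time_bins} exceeds sample count {n}")
    mag = np.abs(coefs)
    edges = np.linspace(0, n, time_bins + 1).round().astype(int)
    out = np.empty((coefs.shape[0], time_bins))
    for b in range(time_bins):
        out[:, b] = mag[:, edges[b]:edges[b + 1]].mean(axis=1)
    return out


def _normalize01(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi - lo <= 0:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def _to_square(m: np.ndarray, size: int) -> np.ndarray:
    if m.shape == (size, size):
        return m
    return _resize(m, (size, size), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)


def render_image(maps: list[np.ndarray], config: CWTConfig,
                 trial_id: int = -1, label: int = -1) -> TFImage:
    """Combine magnitude maps into one RGB image.

    mean_colormap: elementwise mean -> min-max -> resize -> jet LUT.
    ovr_planes: one normalized map per color plane (requires 1-3 maps).
    Rows are flipped so low frequencies sit at the bottom of the image.
    """
    if not maps:
        raise ValueError("need at least one magnitude map")
    maps = [np.asarray(m, dtype=float) for m in maps]
    if len({m.shape for m in maps}) != 1:
        raise ValueError("maps must share a shape")
    size = config.image_size
    if config.image_mode == "ovr_planes":
        if len(maps) > 3:
            raise ValueError("ovr_planes supports at most 3 maps")
        planes = [_to_square(_normalize01(m), size)[::-1] for m in maps]
        while len(planes) < 3:
            planes.append(np.zeros((size, size)))
        pixels = np.clip(np.stack(planes, axis=2), 0, 1)
    else:
        mean_map = np.mean(maps, axis=0)
        norm = _to_square(_normalize01(mean_map), size)[::-1]
        idx = np.clip((norm * (len(_JET) - 1)).round().astype(int),
                      0, len(_JET) - 1)
        pixels = _JET[idx]
    return TFImage(pixels=pixels, trial_id=trial_id, label=label)


def trial_to_image(trial: np.ndarray, models: list[CSPModel], m: int,
                   config: CWTConfig, fs: float,
                   trial_id: int = -1, label: int = -1) -> TFImage:
    """project -> head/tail rows -> CWT -> scalogram -> image, per trial."""
    trial = np.asarray(trial)
    M = models[0].n_channels
    if 2 * m >= M:
        raise ValueError(f"2m = {2 * m} must be < channel count {M}")
    rows = list(range(m)) + list(range(M - m, M))
    maps = []
    for model in models:
        z = project(model, trial)
        for r in rows:
            coefs = morlet_cwt(z[r], fs, config)
            sg = scalogram(coefs, config.time_bins)
            maps.append(sg ** config.magnitude_power
                        if config.magnitude_power != 1.0 else sg)
    if config.image_mode == "ovr_planes" and len(maps) > 3:
        # fold the per-model head/tail pair into one plane per model
        maps = [np.mean(maps[i:i + 2 * m], axis=0)
                for i in range(0, len(maps), 2 * m)]
    return render_image(maps, config, trial_id=trial_id, label=label)


def epochs_to_images(epochs: EEGEpochSet, models: list[CSPModel], m: int,
                     config: CWTConfig) -> np.ndarray:
    """Image tensor (trials, 3, H, W) ready for the image branch."""
    out = np.empty((epochs.n_trials, 3, config.image_size, config.image_size),
                   dtype=np.float32)
    for i in range(epochs.n_trials):
        img = trial_to_image(epochs.data[i], models, m, config, epochs.fs,
                             trial_id=i, label=int(epochs.labels[i]))
        out[i] = img.pixels.transpose(2, 0, 1)
    return out
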