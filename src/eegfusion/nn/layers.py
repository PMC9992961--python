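"""Minimal CPU neural-network layers with explicit backprop.

All layers operate on float32 NCHW tensors and keep whatever state the
backward pass needs from the most recent forward call.  Parameters are
exposed as ``params()`` -> list of (name, array, grad-array) triples so an
optimizer can update them in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "MaxPool2d",
    "Dense",
    "Flatten",
    "ReLU",
    "Softplus",
]

_F32 = np.float32


class Layer:
    """Base class: stateless unless a subclass stores parameters."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []

    def out_shape(self, in_shape: tuple) -> tuple:
        """Shape of a single sample (no batch axis) after this layer."""
        raise NotImplementedError


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Softplus(Layer):
    """ln(1 + e^a); optional smooth activation variant."""

    def forward(self, x, train=False):
        self._x = x
        return np.logaddexp(0.0, x).astype(x.dtype)

    def backward(self, grad):
        return grad / (1.0 + np.exp(-self._x))

    def out_shape(self, in_shape):
        return in_shape


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def out_shape(self, in_shape):
        return (self.W.shape[1],)


class Conv2d(Layer):
    """2-D cross-correlation, stride 1, 'valid' or 'same' padding.

    Kernel shape (F, C, kh, kw).  Implemented with sliding-window views and
    one matmul per call; the backward input gradient is assembled by kh*kw
    shifted slice-adds (cheap for the 3x3 / 3x1 kernels used here).
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator, padding: str = "valid"):
        kh, kw = kernel
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        fan_in = c_in * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((c_out, c_in, kh, kw)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = (kh, kw)
        self.padding = padding

    def _pad(self, x):
        kh, kw = self.kernel
        if self.padding == "same":
            ph, pw = (kh - 1) // 2, (kw - 1) // 2
            ph2, pw2 = kh - 1 - ph, kw - 1 - pw
            return np.pad(x, ((0, 0), (0, 0), (ph, ph2), (pw, pw2)))
        return x

    def forward(self, x, train=False):
        kh, kw = self.kernel
        xp = self._pad(x)
        B, C, H, W = xp.shape
        Ho, Wo = H - kh + 1, W - kw + 1
        # (B, C, Ho, Wo, kh, kw) view -> (B*Ho*Wo, C*kh*kw)
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
        if train:
            self._cols = cols
            self._xp_shape = xp.shape
        F = self.W.shape[0]
        out = cols @ self.W.reshape(F, -1).T + self.b
        return np.ascontiguousarray(
            out.reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2))

    def backward(self, grad):
        kh, kw = self.kernel
        B, F, Ho, Wo = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, F)
        self.dW[...] = (g.T @ self._cols).reshape(self.W.shape)
        self.db[...] = g.sum(axis=0)
        dcols = g @ self.W.reshape(F, -1)  # (B*Ho*Wo, C*kh*kw)
        Bp, C, Hp, Wp = self._xp_shape
        dcols = dcols.reshape(B, Ho, Wo, C, kh, kw)
        dxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.padding == "same":
            return self._crop(dxp)
        return dxp

    def _crop(self, dxp):
        kh, kw = self.kernel
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        ph2, pw2 = kh - 1 - ph, kw - 1 - pw
        H = dxp.shape[2] - ph - ph2
        W = dxp.shape[3] - pw - pw2
        return dxp[:, :, ph:ph + H, pw:pw + W]

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def out_shape(self, in_shape):
        C, H, W = in_shape
        kh, kw = self.kernel
        if self.padding == "same":
            return (self.W.shape[0], H, W)
        Ho, Wo = H - kh + 1, W - kw + 1
        if Ho < 1 or Wo < 1:
            raise ValueError(
                f"input {H}x{W} too small for valid conv kernel {kh}x{kw}")
        return (self.W.shape[0], Ho, Wo)


class MaxPool2d(Layer):
    """Max pooling, stride = pool size, trailing remainder dropped."""

    def __init__(self, pool: tuple[int, int]):
        self.pool = pool

    def forward(self, x, train=False):
        ph, pw = self.pool
        if ph > 2 or pw > 2:
            raise NotImplementedError("pool factors > 2 are not supported")
        B, C, H, W = x.shape
        Ho, Wo = H // ph, W // pw
        if Ho < 1 or Wo < 1:
            raise ValueError(f"input {H}x{W} too small for pool {ph}x{pw}")
        # pairwise max along each pooled axis (pool factors are 1 or 2);
        # ties deterministically favor the first element
        if pw == 2:
            a, b = x[..., 0:2 * Wo:2], x[..., 1:2 * Wo:2]
            mw = a >= b
            u = np.where(mw, a, b)
        else:
            mw, u = None, x
        if ph == 2:
            a, b = u[:, :, 0:2 * Ho:2, :], u[:, :, 1:2 * Ho:2, :]
            mh = a >= b
            out = np.where(mh, a, b)
        else:
            mh, out = None, u
        if train:
            self._mw, self._mh = mw, mh
            self._in_shape = x.shape
        return np.ascontiguousarray(out)

    def backward(self, grad):
        ph, pw = self.pool
        B, C, H, W = self._in_shape
        Ho, Wo = H // ph, W // pw
        if self._mh is not None:
            du = np.zeros((B, C, 2 * Ho, Wo), dtype=grad.dtype)
            du[:, :, 0:2 * Ho:2, :] = np.where(self._mh, grad, 0)
            du[:, :, 1:2 * Ho:2, :] = np.where(self._mh, 0, grad)
            if du.shape[2] != H:
                du = np.concatenate(
                    [du, np.zeros((B, C, H - 2 * Ho, Wo), dtype=grad.dtype)],
                    axis=2)
        else:
            du = grad
        if self._mw is not None:
            dx = np.zeros(self._in_shape, dtype=grad.dtype)
            dx[..., 0:2 * Wo:2] = np.where(self._mw, du, 0)
            dx[..., 1:2 * Wo:2] = np.where(self._mw, 0, du)
        else:
            dx = du
            if dx.shape != self._in_shape:
                full = np.zeros(self._in_shape, dtype=grad.dtype)
                full[:, :, :dx.shape[2], :] = dx
                dx = full
        return dx

    def out_shape(self, in_shape):
        C, H, W = in_shape
        ph, pw = self.pool
        Ho, Wo = H // ph, W // pw
        if Ho < 1 or Wo < 1:
            raise ValueError(f"input {H}x{W} too small for pool {ph}x{pw}")
        return (C, Ho, Wo)
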