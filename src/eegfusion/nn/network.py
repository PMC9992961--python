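"""Sequential container, softmax cross-entropy loss, Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Dense, Layer

__all__ = ["Sequential", "softmax", "cross_entropy_grad", "Adam"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Sequential:
    """Ordered layer stack with a designated penultimate feature tap.

    ``feature_cut`` is the index of the first layer *excluded* from
    feature extraction; by convention the final Dense classifier head.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.feature_cut = max(
            i for i, l in enumerate(layers) if isinstance(l, Dense))
        # validate shape arithmetic at build time
        shape = self.input_shape
        self._shapes = [shape]
        for layer in layers:
            shape = layer.out_shape(shape)
            self._shapes.append(shape)

    @property
    def output_shape(self) -> tuple:
        return self._shapes[-1]

    @property
    def feature_dim(self) -> int:
        return int(np.prod(self._shapes[self.feature_cut]))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def features(self, x: np.ndarray) -> np.ndarray:
        """Activations entering the classifier head (penultimate layer)."""
        for layer in self.layers[:self.feature_cut]:
            x = layer.forward(x, train=False)
        return x.reshape(x.shape[0], -1)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                out.append((f"{i}.{name}", p, g))
        return out

    def state_bytes(self) -> bytes:
        """Deterministic byte serialization of all parameters."""
        chunks = []
        for name, p, _ in self.params():
            chunks.append(name.encode())
            chunks.append(np.ascontiguousarray(p).tobytes())
        return b"".join(chunks)

    def save_npz(self, path):
        np.savez(path, **{name: p for name, p, _ in self.params()})

    def load_npz(self, path):
        with np.load(path) as f:
            for name, p, _ in self.params():
                p[...] = f[name]


class Adam:
    def __init__(self, net: Sequential, lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in net.params()]
        self.v = [np.zeros_like(p) for _, p, _ in net.params()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for (_, p, g), m, v in zip(self.net.params(), self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
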