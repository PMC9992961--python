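"""The two CNN branches: a raw-EEG temporal CNN and a VGG16-style image CNN.

Both expose class logits for standalone training and penultimate-layer
activations for feature fusion.  Training uses Adam (beta1=0.9,
beta2=0.999, initial lr 0.01 by default) on softmax cross-entropy and is
fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, Conv2d, Dense, Flatten, MaxPool2d, ReLU, Sequential,
                 Softplus, cross_entropy_grad, softmax)

__all__ = ["EEGCNNConfig", "TFCNNConfig", "TrainConfig", "TrainedBranch",
           "build_eeg_cnn", "build_tf_cnn", "train_branch",
           "extract_features", "predict_labels", "relu"]

#: VGG16 convolutional widths; pooling follows the marked layers.
_VGG_WIDTHS = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)
_VGG_POOL_AFTER = frozenset({1, 3, 6, 9, 12})


def relu(a):
    """max(0, a) elementwise."""
    return np.maximum(0, a)


@dataclass
class EEGCNNConfig:
    """Two conv(3x1, stride 1, valid) + pool(2x1, stride 2) blocks, one
    hidden fully connected layer, then the class head."""
    filters: tuple[int, int] = (16, 32)
    kernel: tuple[int, int] = (1, 3)   # 1 across EEG channels, 3 in time
    pool: tuple[int, int] = (1, 2)
    fc_units: int = 128
    n_classes: int = 2
    activation: str = "relu"  # or "softplus"

    def __post_init__(self):
        if self.fc_units < self.n_classes:
            raise ValueError("fc_units must be >= n_classes")


@dataclass
class TFCNNConfig:
    """13 conv(3x3, stride 1, same) + 5 pool(2x2, stride 2) stages + 3 FC."""
    width_multiplier: float = 1.0
    fc_units: int | None = None  # default 4096 * width_multiplier
    n_classes: int = 2
    activation: str = "relu"

    def __post_init__(self):
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")
        if self.fc_units is None:
            self.fc_units = max(self.n_classes,
                                int(round(4096 * self.width_multiplier)))


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0


@dataclass
class TrainedBranch:
    net: Sequential
    config: object
    history: list[dict] = field(default_factory=list)

    @property
    def feature_dim(self) -> int:
        return self.net.feature_dim


def _act(name: str):
    if name == "relu":
        return ReLU()
    if name == "softplus":
        return Softplus()
    raise ValueError(f"unknown activation {name!r}")


def build_eeg_cnn(config: EEGCNNConfig, input_shape: tuple[int, int],
                  seed: int = 0) -> Sequential:
    """Network over (1, channels, samples) input; errors at build time if
    the time axis collapses below 1 in any stage."""
    channels, samples = input_shape
    rng = np.random.default_rng([seed, 1])
    layers = []
    c_in = 1
    for f in config.filters:
        layers += [Conv2d(c_in, f, config.kernel, rng, padding="valid"),
                   _act(config.activation),
                   MaxPool2d(config.pool)]
        c_in = f
    layers += [Flatten()]
    # probe the flattened width via shape arithmetic
    probe = Sequential(layers + [Dense(1, 1, rng)], (1, channels, samples))
    flat = int(np.prod(probe._shapes[len(layers)]))
    layers += [Dense(flat, config.fc_units, rng), _act(config.activation),
               Dense(config.fc_units, config.n_classes, rng)]
    return Sequential(layers, (1, channels, samples))


def build_tf_cnn(config: TFCNNConfig, image_size: int = 64,
                 seed: int = 0) -> Sequential:
    rng = np.random.default_rng([seed, 2])
    wm = config.width_multiplier
    layers = []
    c_in = 3
    spatial = image_size
    for i, w in enumerate(_VGG_WIDTHS):
        c_out = max(1, int(round(w * wm)))
        layers += [Conv2d(c_in, c_out, (3, 3), rng, padding="same"),
                   _act(config.activation)]
        c_in = c_out
        if i in _VGG_POOL_AFTER:
            layers.append(MaxPool2d((2, 2)))
            spatial //= 2
    if spatial < 1:
        raise ValueError(f"image size {image_size} too small for 5 pool stages")
    flat = c_in * spatial * spatial
    layers += [Flatten(),
               Dense(flat, config.fc_units, rng), _act(config.activation),
               Dense(config.fc_units, config.fc_units, rng),
               _act(config.activation),
               Dense(config.fc_units, config.n_classes, rng)]
    return Sequential(layers, (3, image_size, image_size))


def _as_net_input(net: Sequential, inputs: np.ndarray) -> np.ndarray:
    x = np.asarray(inputs, dtype=np.float32)
    want = net.input_shape
    if x.shape[1:] == want:
        return x
    if x.shape[1:] == want[1:] and want[0] == 1:  # add singleton plane
        return x[:, None, :, :]
    raise ValueError(f"input shape {x.shape[1:]} incompatible with {want}")


def train_branch(net: Sequential, dataset, train_config: TrainConfig) -> TrainedBranch:
    """Minibatch Adam on softmax cross-entropy; aborts on NaN loss."""
    inputs, labels = dataset
    x = _as_net_input(net, inputs)
    y = np.asarray(labels, dtype=np.int64)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain >= 2 classes")
    n_classes = net.output_shape[0]
    if y.max() >= n_classes:
        raise ValueError(f"label {y.max()} out of range for {n_classes}-way head")
    opt = Adam(net, lr=train_config.learning_rate,
               beta1=train_config.beta1, beta2=train_config.beta2)
    rng = np.random.default_rng([train_config.seed, 3])
    history = []
    n = len(y)
    bs = min(train_config.batch_size, n)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for s in range(0, n, bs):
            idx = order[s:s + bs]
            logits = net.forward(x[idx], train=True)
            loss, grad = cross_entropy_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning rate")
            net.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history.append({"epoch": epoch,
                        "loss": float(np.sum(losses) / n),
                        "accuracy": correct / n})
    return TrainedBranch(net=net, config=train_config, history=history)


def extract_features(branch: TrainedBranch, inputs: np.ndarray) -> np.ndarray:
    """Penultimate fully-connected activations (post-activation)."""
    x = _as_net_input(branch.net, inputs)
    return branch.net.features(x)


def predict_labels(branch: TrainedBranch, inputs: np.ndarray) -> np.ndarray:
    x = _as_net_input(branch.net, inputs)
    return softmax(branch.net.forward(x)).argmax(axis=1)
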