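import numpy as np
import pytest

from eegfusion.data import EEGEpochSet
from eegfusion.preprocess import preprocess
from eegfusion.synth import SynthConfig, generate_mi_dataset


@pytest.fixture(scope="session")
def small_binary():
    """Preprocessed strongly-separable binary dataset, 20 trials/class."""
    cfg = SynthConfig(n_classes=2, n_trials_per_class=20, erd_depth=0.8,
                      seed=7)
    return preprocess(generate_mi_dataset(cfg))


@pytest.fixture(scope="session")
def tiny_binary():
    """Very small/short dataset for expensive per-test pipelines."""
    cfg = SynthConfig(n_classes=2, n_trials_per_class=10, n_channels=8,
                      duration=2.0, erd_depth=0.8, seed=11)
    return generate_mi_dataset(cfg)


@pytest.fixture(scope="session")
def three_class():
    cfg = SynthConfig(n_classes=3, n_trials_per_class=12, n_channels=10,
                      duration=2.0, erd_depth=0.7, seed=13)
    return generate_mi_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochs(data, labels, fs=250.0, channel_names=None, class_names=None):
    data = np.asarray(data, dtype=float)
    channel_names = channel_names or [f"CH{i}" for i in range(data.shape[1])]
    return EEGEpochSet(data, np.asarray(labels), fs, channel_names,
                       class_names or [])
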