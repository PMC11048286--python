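"""Shared fixtures: synthetic recordings, EDF files and desk-scale tasks.

All fixture data is generated programmatically at test time; nothing is
stored on disk in the repository.
"""

import numpy as np
import pytest

from cst.io import EEGRecord, EpochSet
from cst.model import ModelConfig, TrainConfig
from cst.synth import make_dataset, two_class_alpha_task


@pytest.fixture
def sine_record():
    """2-channel 256 Hz, 10 s record: 10 Hz sine + white noise."""
    fs = 256
    t = np.arange(10 * fs) / fs
    rng = np.random.default_rng(0)
    data = np.stack([
        50 * np.sin(2 * np.pi * 10 * t),
        10 * rng.standard_normal(len(t)),
    ])
    return EEGRecord(data, fs, ["C3", "C4"], subject_id="s01",
                     annotations=[(3.0, 1.5, "seizure")])


@pytest.fixture
def edf_file(tmp_path, sine_record):
    from cst.io import write_edf
    return write_edf(sine_record, tmp_path / "rec.edf")


def small_epochset(n_per_class=10, T=64, C=3, n_classes=2, seed=0):
    """Random labelled epochs with round-robin groups (no class signal)."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    epochs = rng.standard_normal((n, T, C))
    labels = np.repeat(np.arange(n_classes), n_per_class)
    groups = [f"g{i % 4}" for i in range(n)]
    return EpochSet(epochs, labels, 64.0, [f"c{i}" for i in range(n_classes)],
                    groups)


@pytest.fixture
def random_epochs():
    return small_epochset()


@pytest.fixture(scope="session")
def tiny_task():
    """A fast, strongly separable two-class task for training tests."""
    spec = two_class_alpha_task(n_per_class=24, C=3, fs=64.0, window_s=1.0,
                                gain=4.0, seed=11)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model_cfg(tiny_task):
    return ModelConfig(in_channels=tiny_task.n_channels,
                       n_classes=tiny_task.n_classes,
                       n_sparse_layers=1, n_full_layers=1,
                       n_conv_layers=2, n_pool_layers=2,
                       d_model=16, d_ff=32, n_heads=2, seed=5)


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return TrainConfig(epochs=3, batch_size=16, learning_rate=1e-3, seed=5)


# ---- the desk-scale benchmark shared by the heavier protocol tests --------

@pytest.fixture(scope="session")
def desk_task():
    """Two-class 4-channel 128 Hz 4 s task, 200 epochs per class, gain 3."""
    return make_dataset(two_class_alpha_task())


@pytest.fixture(scope="session")
def desk_model_cfg(desk_task):
    """Reduced encoder: 2 sparse + 1 full layer, 3 distills, d_model 64."""
    return ModelConfig(in_channels=desk_task.n_channels,
                       n_classes=desk_task.n_classes,
                       n_sparse_layers=2, n_full_layers=1,
                       n_conv_layers=3, n_pool_layers=3,
                       d_model=64, d_ff=128, n_heads=8, seed=7)


@pytest.fixture(scope="session")
def desk_train_cfg():
    return TrainConfig(epochs=3, batch_size=32, learning_rate=1e-3, seed=7)
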