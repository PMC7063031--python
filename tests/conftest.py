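import numpy as np
import pytest

from emglens.adann import TrainConfig, train_adann
from emglens.convnet import ArchitectureConfig, build_model
from emglens.handcrafted import build_registry, compute_all
from emglens.signal_io import WindowedDataset
from emglens.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(participants=3, gestures=3, cycle_duration=0.5,
                       cycles=4, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """3 participants x 3 gestures x 4 cycles of 0.5 s -> 252 windows."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_table(small_dataset, registry):
    """Handcrafted features on a thinned subset (every 3rd window)."""
    subset = WindowedDataset(small_dataset.windows[::3],
                             dict(small_dataset.split))
    return compute_all(subset, registry)


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchitectureConfig(n_blocks=2, feature_maps=4, n_classes=3)


@pytest.fixture(scope="session")
def trained_tiny_model(small_dataset, tiny_arch):
    """A briefly ADANN-trained tiny model on the small synthetic dataset."""
    model = build_model(tiny_arch, seed=3)
    train_adann(model, small_dataset,
                TrainConfig(lr=2e-3, batch_size=128, max_epochs=6, seed=3))
    return model
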