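import numpy as np
import pytest

from spikerhythm.datasets import build_dataset
from spikerhythm.sae import SAEConfig


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 4-class archetype dataset (length-32 sequences) for fast tests."""
    return build_dataset({"n_train_per_class": 6, "n_test_per_class": 3,
                          "length": 32}, seed=42)


@pytest.fixture(scope="session")
def tiny_config():
    """Down-scaled network matching the length-32 fixture."""
    return SAEConfig(layer_sizes=(32, 16, 8), unsup_epochs=80, sup_epochs=80)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
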