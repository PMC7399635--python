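import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from promoter5mc import (
    GeneratorConfig,
    SubModelConfig,
    generate_dataset,
    train_ensemble,
)

FAST_CONFIG = SubModelConfig(hidden_layers=[32, 64, 32], epochs=40, batch_size=64)


@pytest.fixture(scope="session")
def small_dataset():
    """Strong-signal labeled windows at delta=5, 1:11 imbalance."""
    return generate_dataset(
        GeneratorConfig(n_pos=60, n_neg=660, delta=5, effect=0.9, seed=11)
    )


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A 3-sub-model ensemble trained on the small strong-signal dataset."""
    return train_ensemble(small_dataset, k=3, config=FAST_CONFIG, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
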