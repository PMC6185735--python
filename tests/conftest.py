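import numpy as np
import pytest

from pcanlm import (
    NLMConfig,
    PatchConfig,
    SpeckleParams,
    add_speckle,
    make_geometric_phantom,
    make_training_corpus,
    train_pcanet,
)


@pytest.fixture(scope="session")
def geometric_clean() -> np.ndarray:
    return make_geometric_phantom((128, 128), seed=0)


@pytest.fixture(scope="session")
def noisy_sigma3(geometric_clean) -> np.ndarray:
    return add_speckle(geometric_clean, SpeckleParams(sigma=3.0, seed=7))


@pytest.fixture(scope="session")
def small_model():
    """Reduced model (4x4 filters, 10-image corpus) for desk-scale runs."""
    corpus = make_training_corpus(n=10, size=(128, 128), sigma=3.0, seed=1)
    return train_pcanet(corpus, PatchConfig(7, 7), L1=4, L2=4)


@pytest.fixture(scope="session")
def default_nlm_config() -> NLMConfig:
    return NLMConfig(sigma=3.0)
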