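import numpy as np
import pytest

from sparsestruct import synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_symmetric():
    """A small symmetric ensemble shared across fast tests."""
    x, a, spec = synth.symmetric_ensemble(n_dims=16, n_elements=16,
                                          n_samples=3000, seed=11)
    return x, a, spec


@pytest.fixture(scope="session")
def small_skewed():
    x, a, spec = synth.skewed_ensemble(n_dims=32, n_elements=16,
                                       n_samples=3000, seed=12)
    return x, a, spec
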