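import numpy as np
import pytest

from nsrff.spectral import (
    FrequencyMatrix,
    FrequencyPairSet,
    SpectralSpec,
    sample_frequencies,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_design(rng):
    """A 30-point 2-D design with responses from a smooth function."""
    X = rng.uniform(0, 1, size=(30, 2))
    y = np.sin(3 * X[:, 0]) + 0.5 * np.cos(5 * X[:, 1]) + 0.05 * rng.standard_normal(30)
    return X, y


@pytest.fixture
def gaussian_spec():
    return SpectralSpec(family="gaussian", dim=2, lengthscales=[0.5, 1.0])


@pytest.fixture
def frequency_pair(rng):
    W1 = FrequencyMatrix(rng.normal(size=(6, 2)))
    W2 = FrequencyMatrix(rng.normal(size=(6, 2)))
    return FrequencyPairSet(W1, W2)
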