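import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_binary_data(rng):
    """Linearly separable-ish 2-class data, 40 x 4."""
    n = 20
    X0 = rng.normal(0.0, 1.0, size=(n, 4))
    X1 = rng.normal(1.5, 1.0, size=(n, 4))
    X = np.vstack([X0, X1])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y
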