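import numpy as np
import pytest


def random_correlation(rng, p, n=None):
    """Sample correlation matrix of random Gaussian data (generic test input)."""
    X = rng.standard_normal((n or p + 5, p))
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return R


def random_mask(rng, p, density=0.5):
    """Random symmetric binary mask with unit diagonal."""
    U = rng.random((p, p)) < density
    W = np.triu(U, 1)
    W = W | W.T
    np.fill_diagonal(W, True)
    return W


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
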