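import numpy as np
import pytest

from phasemark.datatypes import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """2 samples x 3 probes with one missing cell."""
    vals = np.array([[1.0, 2.0, np.nan], [4.0, 5.0, 6.0]])
    return ExpressionMatrix(["s1", "s2"], ["p1", "p2", "p3"], vals)


@pytest.fixture
def blob_data():
    """Two well-separated Gaussian blobs (10 sigma apart), fixed seed."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, size=(15, 8))
    b = rng.normal(10.0, 1.0, size=(15, 8))
    X = np.vstack([a, b])
    labels = np.array([0] * 15 + [1] * 15)
    return X, labels


def random_matrix(n: int, p: int, seed: int = 0) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        [f"s{i}" for i in range(n)],
        [f"p{j}" for j in range(p)],
        rng.normal(size=(n, p)),
    )
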