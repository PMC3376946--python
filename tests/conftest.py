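import numpy as np
import pytest

from realml.data import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_dataset(rng):
    """Unstructured binary data: 60 instances, 12 features, 3 labels."""
    return Dataset(
        rng.integers(0, 2, (60, 12)),
        rng.integers(0, 2, (60, 3)),
    )


@pytest.fixture
def separable_dataset():
    """Two labels copied from two disjoint single features, noise elsewhere.

    Label 0 equals feature 0 and label 1 equals feature 3 exactly, so a
    one-feature subspace per label carries perfect information.
    """
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, (40, 6))
    Y = np.stack([X[:, 0], X[:, 3]], axis=1)
    return Dataset(X, Y)
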