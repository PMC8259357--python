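import numpy as np
import pytest

from lppflip import MISSING, GenotypeMatrix


@pytest.fixture
def conflict_2x2():
    """The minimal non-linear matrix: disjoint one-states."""
    return GenotypeMatrix(np.array([[1, 0], [0, 1]]))


@pytest.fixture
def linear_2x2():
    return GenotypeMatrix(np.array([[1, 1], [0, 1]]))


@pytest.fixture
def missing_3x2():
    return GenotypeMatrix(np.array([[MISSING, 0], [1, 1], [0, 1]]))


def random_binary_matrix(rng, n_max=10, m_max=5, missing_frac=0.0):
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    M = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random((n, m)) < missing_frac
        M[mask] = MISSING
    return GenotypeMatrix(M)
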