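import numpy as np
import pytest

from funchill import AbundanceVector, DistanceMatrix
from funchill.datasets import example1_communities, example2_matrices


@pytest.fixture(scope="session")
def desk_example():
    """Four-species ultrametric/non-ultrametric matrices and the two
    completely distinct two-species assemblages."""
    case1, case2, Z = example2_matrices()
    return case1, case2, Z


@pytest.fixture(scope="session")
def case1(desk_example):
    return desk_example[0]


@pytest.fixture(scope="session")
def case2(desk_example):
    return desk_example[1]


@pytest.fixture(scope="session")
def two_assemblages(desk_example):
    return desk_example[2]


@pytest.fixture(scope="session")
def equal_p4(case1):
    return AbundanceVector(case1.labels, np.full(4, 0.25))


@pytest.fixture(scope="session")
def shared_layout():
    """20+20 species with 12 shared, equal abundances."""
    return example1_communities("equal")


@pytest.fixture
def constant_dm():
    def make(labels, c=1.0, diagonal=True):
        v = np.full((len(labels), len(labels)), c, dtype=float)
        if not diagonal:
            np.fill_diagonal(v, 0.0)
        return DistanceMatrix(tuple(labels), v)

    return make
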