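import numpy as np
import pytest

from phagenet import InfectionMatrix


def random_matrix(rng, max_r=12, max_c=12, min_r=2, min_c=2):
    """Random binary labelled matrix with at least one interaction."""
    r = int(rng.integers(min_r, max_r + 1))
    c = int(rng.integers(min_c, max_c + 1))
    while True:
        a = (rng.random((r, c)) < rng.uniform(0.15, 0.85)).astype(np.int8)
        if a.sum() >= 1:
            break
    return InfectionMatrix(a,
                           tuple(f"PT{i}" for i in range(r)),
                           tuple(f"TP{j}" for j in range(c)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def staircase3():
    """Perfectly nested 3x3 staircase."""
    return InfectionMatrix([[1, 1, 1], [1, 1, 0], [1, 0, 0]],
                           ("a", "b", "c"), ("x", "y", "z"))


@pytest.fixture
def identity2():
    return InfectionMatrix(np.eye(2, dtype=int), ("b1", "b2"), ("p1", "p2"))
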