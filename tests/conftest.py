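import numpy as np
import pytest

from corrnull import FoodWeb, IncidenceMatrix


@pytest.fixture
def identity2():
    return IncidenceMatrix(np.eye(2, dtype=int), ["r1", "r2"], ["c1", "c2"])


@pytest.fixture
def nested3():
    """Strictly nested 3×3 triangle: all marginals distinct, full overlap."""
    return IncidenceMatrix(
        [[1, 1, 1], [1, 1, 0], [1, 0, 0]], ["A", "B", "C"], ["x", "y", "z"]
    )


@pytest.fixture
def chain_web():
    """a eats b, b eats c, plus the omnivory link a eats c."""
    return FoodWeb(
        np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]]), ["a", "b", "c"]
    )


@pytest.fixture
def small_matrix_4x4():
    """4×4 with 6 links; its fixed-marginal class is small enough to enumerate."""
    return IncidenceMatrix(
        np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]]),
        ["r1", "r2", "r3", "r4"],
        ["c1", "c2", "c3", "c4"],
    )
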