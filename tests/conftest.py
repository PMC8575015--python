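import numpy as np
import pytest

from markerpanel import (
    ExpressionMatrix,
    difference_tensor,
    specificity_scores,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 cell types × 6 genes, deterministic, with one obvious marker (g0)."""
    rng = np.random.default_rng(42)
    S = rng.gamma(2.0, 20.0, size=(4, 6))
    S[:, 0] = [200.0, 5.0, 5.0, 5.0]  # g0: specific to c0
    return ExpressionMatrix(
        ("c0", "c1", "c2", "c3"),
        ("g0", "g1", "g2", "g3", "g4", "g5"),
        S,
    )


@pytest.fixture
def small_tensor(small_matrix):
    return difference_tensor(small_matrix)


@pytest.fixture
def small_specificity(small_matrix):
    return specificity_scores(small_matrix)


def random_instance(rng, m=None, n=None):
    """A random valid expression matrix for property tests."""
    m = m or int(rng.integers(3, 7))
    n = n or int(rng.integers(6, 13))
    S = rng.gamma(2.0, 20.0, size=(m, n))
    return ExpressionMatrix(
        tuple(f"c{i}" for i in range(m)),
        tuple(f"g{i}" for i in range(n)),
        S,
    )
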