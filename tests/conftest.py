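import numpy as np
import pytest

from ultranet import LabeledDissimilarity

#: the 4-point path-like instance used throughout: the unique MST is a-b-c-d
CANONICAL_WEIGHTS = {
    ("a", "b"): 1.0,
    ("b", "c"): 2.0,
    ("c", "d"): 3.0,
    ("a", "c"): 4.0,
    ("a", "d"): 5.0,
    ("b", "d"): 6.0,
}

#: its subdominant ultrametric (minimax path values), frozen from the
#: Floyd-Warshall bottleneck closure and cross-checked by path enumeration
CANONICAL_WSTAR = {
    ("a", "b"): 1.0,
    ("b", "c"): 2.0,
    ("a", "c"): 2.0,
    ("c", "d"): 3.0,
    ("a", "d"): 3.0,
    ("b", "d"): 3.0,
}


@pytest.fixture
def canonical() -> LabeledDissimilarity:
    return LabeledDissimilarity.from_pairs("abcd", CANONICAL_WEIGHTS)


@pytest.fixture
def triangle() -> LabeledDissimilarity:
    """Equilateral unit triangle: all three spanning trees tie."""
    return LabeledDissimilarity.from_pairs(
        "abc", {("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0}
    )


def random_dissimilarity(rng: np.random.Generator, n: int, integer: bool = False):
    """A random complete positive dissimilarity on n labelled points.

    Integer weights are drawn from a small range to force MST ties.
    """
    if integer:
        m = rng.integers(1, 6, size=(n, n)).astype(float)
    else:
        m = rng.uniform(0.1, 10.0, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    return LabeledDissimilarity(tuple(f"v{i:02d}" for i in range(n)), m)
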