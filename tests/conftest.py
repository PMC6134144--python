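import numpy as np
import pytest

from cellspring import ClassAssignment, ExpressionMatrix, ProfileSpace


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 genes x 4 cells raw counts, two classes of two cells."""
    values = np.array(
        [
            [5, 1, 0, 2],
            [3, 2, 7, 1],
            [0, 1, 1, 9],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        values=values,
        gene_ids=("g1", "g2", "g3"),
        cell_ids=("c1", "c2", "c3", "c4"),
    )


@pytest.fixture
def small_classes() -> ClassAssignment:
    return ClassAssignment({"c1": "A", "c2": "A", "c3": "B", "c4": "B"})


def random_profile_space(n: int, seed: int) -> ProfileSpace:
    """A valid random correlation-profile space (corr matrix of random data)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n + 5))
    corr = np.corrcoef(X)
    corr = np.clip((corr + corr.T) / 2, -1, 1)
    np.fill_diagonal(corr, 1.0)
    return ProfileSpace(corr, tuple(f"c{i}" for i in range(n)))
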