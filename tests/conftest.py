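import numpy as np
import pytest

from hapscreen.matrix import CountMatrix


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """Five genes, 2-vs-2, hand-chosen integers (small enough to enumerate)."""
    counts = np.array(
        [
            [10, 12, 20, 22],   # clear shift
            [5, 5, 5, 5],       # constant
            [100, 90, 95, 105], # noise
            [3, 30, 12, 14],    # noisy within treated
            [50, 55, 20, 18],   # clear shift the other way
        ]
    )
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(5)],
        sample_ids=["t1", "t2", "c1", "c2"],
        group_of={"t1": "treated", "t2": "treated", "c1": "control", "c2": "control"},
        counts=counts,
    )


@pytest.fixture
def flagged_matrix() -> CountMatrix:
    rng = np.random.default_rng(11)
    n = 10
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(n)],
        sample_ids=["t1", "t2", "c1", "c2"],
        group_of={"t1": "treated", "t2": "treated", "c1": "control", "c2": "control"},
        counts=rng.integers(0, 50, size=(n, 4)),
        rrna_flags=np.array([i in (1, 4, 7) for i in range(n)]),
    )
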