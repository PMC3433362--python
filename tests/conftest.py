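import numpy as np
import pytest

from mitdbn import DiscreteDataset, TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_discrete():
    """Factory for seeded i.i.d. discrete datasets."""

    def make(n=4, k=2, lengths=(30,), seed=0):
        r = np.random.default_rng(seed)
        series = [r.integers(0, k, size=(n, ln)) for ln in lengths]
        return DiscreteDataset(series, k=k, gene_ids=[f"g{i}" for i in range(n)])

    return make


@pytest.fixture
def copy_chain_dataset():
    """x1 -> x2 -> x3 deterministic lag-1 chain plus noise genes, N=100."""
    r = np.random.default_rng(3)
    n, N = 5, 100
    x = r.integers(0, 2, size=(n, N))
    x[1, 1:] = x[0, :-1]
    x[2, 1:] = x[1, :-1]
    return DiscreteDataset([x], k=2, gene_ids=["x1", "x2", "x3", "n1", "n2"])


@pytest.fixture
def small_tss():
    return TimeSeriesSet(
        [np.array([[1.0, 2, 3, 4, 5, 6, 7, 8, 9], [9, 7, 5, 3, 1, 2, 4, 6, 8]])],
        gene_ids=["a", "b"],
    )
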