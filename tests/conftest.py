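import numpy as np
import pytest

from clonepop.genotype_io import table_from_calls
from clonepop.simulate import make_paper_like_fixture


@pytest.fixture(scope="session")
def paper_bundle():
    """Four study-shaped populations (two species x two sites) with truth."""
    return make_paper_like_fixture(seed=1)


def make_table(calls, pops=None, loci=None, names=None):
    """Small-table helper: calls is (n, L, 2) nested lists or array."""
    arr = np.asarray(calls, dtype=np.int64)
    n, L = arr.shape[0], arr.shape[1]
    return table_from_calls(
        names or [f"ind{i + 1}" for i in range(n)],
        pops or ["popA"] * n,
        loci or [f"L{j + 1}" for j in range(L)],
        arr,
    )


def random_table(rng, n=12, n_loci=4, n_alleles=4, n_pops=1, missing_rate=0.0):
    """Random valid table with allele sizes on a 3-bp ladder."""
    arr = np.sort(rng.integers(1, n_alleles + 1, size=(n, n_loci, 2)), axis=2) * 3 + 100
    if missing_rate:
        mask = rng.random((n, n_loci)) < missing_rate
        arr[mask] = 0
    pops = [f"pop{1 + (i * n_pops) // n}" for i in range(n)]
    return make_table(arr, pops=pops)
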