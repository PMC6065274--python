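import numpy as np
import pytest

from cusipop.types import MISSING, GenotypeMatrix, PopulationMap


def make_matrix(genotypes, individual_ids=None, locus_ids=None, popmap=None):
    """Small-matrix helper: ``genotypes`` is a list (per individual) of
    lists (per locus) of allele pairs, with None for missing."""
    n = len(genotypes)
    L = len(genotypes[0])
    calls = np.full((n, L, 2), MISSING, dtype=np.int32)
    for i, row in enumerate(genotypes):
        for j, g in enumerate(row):
            if g is not None:
                calls[i, j] = g
    ids = individual_ids or [f"ind{i}" for i in range(n)]
    lids = locus_ids or [f"L{j}" for j in range(L)]
    m = GenotypeMatrix(ids, lids, calls)
    if popmap is None:
        popmap = PopulationMap({i: "pop1" for i in ids})
    return m, popmap


def random_matrix(rng, n=6, L=5, n_pops=2, missing_rate=0.1, max_allele=2):
    """Random dense-coded matrix + popmap for round-trip properties."""
    calls = rng.integers(0, max_allele, size=(n, L, 2)).astype(np.int32)
    miss = rng.random((n, L)) < missing_rate
    calls[miss] = MISSING
    ids = [f"i{i}" for i in range(n)]
    m = GenotypeMatrix(ids, [f"l{j}" for j in range(L)], calls).recode_dense()
    pops = {ind: f"p{rng.integers(n_pops)}" for ind in ids}
    return m, PopulationMap(pops)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_fixture():
    from cusipop.synthetic_data import make_study_shaped_fixture

    return make_study_shaped_fixture(seed=42)
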