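import numpy as np
import pytest

from msatpop.io import GenotypeDataset, LocusMeta


def make_random_dataset(
    rng: np.random.Generator,
    n_pops: int = 3,
    n_per_pop: int = 5,
    n_loci: int = 4,
    n_alleles: int = 4,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Random multi-allelic diploid dataset for round-trip/property tests."""
    inds, pops = [], []
    for p in range(n_pops):
        for i in range(n_per_pop):
            inds.append(f"p{p + 1}i{i + 1}")
            pops.append(f"pop{p + 1}")
    N = len(inds)
    alleles = 100 + 2 * np.arange(n_alleles)
    calls = rng.choice(alleles, size=(N, n_loci, 2))
    if missing_rate:
        miss = rng.random((N, n_loci)) < missing_rate
        calls[miss] = -1
    loci = [LocusMeta(f"Loc{l + 1}", motif_length=2) for l in range(n_loci)]
    return GenotypeDataset(inds, pops, loci, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20220810)


@pytest.fixture
def two_pop_one_locus():
    """The hand-checkable two-population, one-locus, two-allele dataset:
    pop1 = 8×A1/A1 + 2×A1/A2, pop2 = 3×A1/A1 + 7×A2/A2."""
    genos = [[1, 1]] * 8 + [[1, 2]] * 2 + [[1, 1]] * 3 + [[2, 2]] * 7
    calls = np.array(genos).reshape(20, 1, 2)
    return GenotypeDataset(
        [f"i{k}" for k in range(20)],
        ["P1"] * 10 + ["P2"] * 10,
        [LocusMeta("L1", motif_length=1)],
        calls,
    )


@pytest.fixture
def fixed_difference_ds():
    """Two populations fixed for different alleles at every locus."""
    calls = np.zeros((20, 3, 2), dtype=int)
    calls[:10] = 10
    calls[10:] = 20
    return GenotypeDataset(
        [f"i{k}" for k in range(20)],
        ["A"] * 10 + ["B"] * 10,
        [LocusMeta(f"L{l}", motif_length=1) for l in range(3)],
        calls,
    )
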