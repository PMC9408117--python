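import numpy as np
import pytest

from msatpop.distances import (
    AlleleSizeMap,
    bootstrap_distance,
    coancestry_fij,
    delta_mu2,
    nei_ds,
)
from msatpop.io import GenotypeDataset, LocusMeta, allele_frequencies
from conftest import make_random_dataset


def ds_from_freq_profiles(profiles, n=50, seed=0):
    """Build a dataset by sampling genotypes from per-population allele
    frequency profiles {pop: {allele: freq}} at one or more loci."""
    rng = np.random.default_rng(seed)
    pops = list(profiles)
    n_loci = len(next(iter(profiles.values())))
    inds, labels, rows = [], [], []
    for pop in pops:
        for i in range(n):
            inds.append(f"{pop}{i}")
            labels.append(pop)
            geno = []
            for locus_profile in profiles[pop]:
                alleles = list(locus_profile)
                p = np.array([locus_profile[a] for a in alleles])
                geno.append(rng.choice(alleles, size=2, p=p / p.sum()))
            rows.append(geno)
    loci = [LocusMeta(f"L{l}", motif_length=1) for l in range(n_loci)]
    return GenotypeDataset(inds, labels, loci, np.array(rows))


def exact_freq_table(pop_freqs):
    """AlleleFrequencyTable with exact frequencies via integer counts."""
    ds_rows = []
    # use 10000 copies scaled counts to express exact decimals
    from msatpop.io import AlleleFrequencyTable, LocusFrequencies

    pops = list(pop_freqs)
    loci = []
    n_loci = len(next(iter(pop_freqs.values())))
    for l in range(n_loci):
        alleles = sorted({a for p in pops for a in pop_freqs[p][l]})
        counts = np.array(
            [[round(10000 * pop_freqs[p][l].get(a, 0.0)) for a in alleles] for p in pops],
            dtype=np.int64,
        )
        loci.append(
            LocusFrequencies(
                f"L{l}",
                np.array(alleles),
                counts,
                np.zeros_like(counts),
                np.full(len(pops), 5000, dtype=np.int64),
            )
        )
    return AlleleFrequencyTable(pops, loci)


class TestCoancestry:
    def test_uniform_diagonal(self):
        f = exact_freq_table({"X": [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}],
                              "Y": [{1: 1.0}]})
        m = coancestry_fij(f)
        assert m.loc("X", "X") == pytest.approx(0.25)

    def test_disjoint_allele_sets_zero(self):
        f = exact_freq_table({"X": [{1: 0.5, 2: 0.5}], "Y": [{3: 0.5, 4: 0.5}]})
        assert coancestry_fij(f).loc("X", "Y") == pytest.approx(0.0)

    def test_worked_example(self):
        """p_X = (0.8, 0.2), p_Y = (0.5, 0.5) → f = 0.8·0.5 + 0.2·0.5 = 0.5."""
        f = exact_freq_table({"X": [{1: 0.8, 2: 0.2}], "Y": [{1: 0.5, 2: 0.5}]})
        assert coancestry_fij(f).loc("X", "Y") == pytest.approx(0.5)

    def test_self_coancestry_dominates(self, rng):
        """f_ii ≥ f_ij (Cauchy–Schwarz on the frequency cross-products)."""
        ds = make_random_dataset(rng, n_pops=3, n_per_pop=15, n_loci=5)
        m = coancestry_fij(allele_frequencies(ds))
        # compare against the average to tolerate sampling asymmetry
        for i in range(m.n):
            for j in range(m.n):
                pair_max = max(m.values[i, i], m.values[j, j])
                assert m.values[i, j] <= pair_max + 1e-12


class TestNeiDs:
    def test_identical_profiles_zero(self):
        f = exact_freq_table({"X": [{1: 0.3, 2: 0.7}], "Y": [{1: 0.3, 2: 0.7}]})
        assert nei_ds(f).loc("X", "Y") == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        """p_X = (1, 0), p_Y = (0.5, 0.5) → −ln(0.5/√0.5) = 0.34657…"""
        f = exact_freq_table({"X": [{1: 1.0}], "Y": [{1: 0.5, 2: 0.5}]})
        assert nei_ds(f).loc("X", "Y") == pytest.approx(np.log(2) / 2, abs=1e-12)

    def test_disjoint_sets_infinite(self):
        f = exact_freq_table({"X": [{1: 1.0}], "Y": [{2: 1.0}]})
        assert np.isinf(nei_ds(f).loc("X", "Y"))


class TestDeltaMu2:
    def test_identical_zero(self):
        f = exact_freq_table({"X": [{10: 1.0}], "Y": [{10: 1.0}]})
        assert delta_mu2(f).loc("X", "Y") == 0.0

    def test_fixed_size_gap(self):
        """X fixed at size 10, Y at size 12 → (10 − 12)² = 4."""
        f = exact_freq_table({"X": [{10: 1.0}], "Y": [{12: 1.0}]})
        assert delta_mu2(f).loc("X", "Y") == pytest.approx(4.0)

    def test_two_locus_average(self):
        """Mean-size gaps 1 and 3 → (1 + 9)/2 = 5."""
        f = exact_freq_table(
            {"X": [{10: 1.0}, {20: 1.0}], "Y": [{11: 1.0}, {23: 1.0}]}
        )
        assert delta_mu2(f).loc("X", "Y") == pytest.approx(5.0)

    def test_bp_conversion(self):
        """bp codes with offset 100 and motif 2: sizes (10, 12) repeat
        units → same distance as the repeat-unit fixture."""
        f = exact_freq_table({"X": [{120: 1.0}], "Y": [{124: 1.0}]})
        sizes = AlleleSizeMap(offsets={"L0": 100}, motif_lengths={"L0": 2})
        assert delta_mu2(f, sizes).loc("X", "Y") == pytest.approx(4.0)

    def test_nonpositive_size_score_rejected(self):
        f = exact_freq_table({"X": [{90: 1.0}], "Y": [{124: 1.0}]})
        sizes = AlleleSizeMap(offsets={"L0": 100}, motif_lengths={"L0": 2})
        with pytest.raises(ValueError, match="L0"):
            delta_mu2(f, sizes)

    def test_symmetry_under_population_order(self, rng):
        ds = make_random_dataset(rng, n_pops=3, n_per_pop=10, n_loci=4)
        f = allele_frequencies(ds)
        m = delta_mu2(f)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)


class TestBootstrap:
    @pytest.mark.parametrize("stat", ["Ds", "dmu2", "fst"])
    def test_same_seed_identical(self, rng, stat):
        f = allele_frequencies(make_random_dataset(rng, n_pops=3, n_loci=5))
        r1 = bootstrap_distance(f, stat, B=10, seed=42)
        r2 = bootstrap_distance(f, stat, B=10, seed=42)
        np.testing.assert_array_equal(r1.locus_indices, r2.locus_indices)
        for a, b in zip(r1.matrices, r2.matrices):
            np.testing.assert_array_equal(a.values, b.values)

    def test_degenerate_identical_loci(self, rng):
        """All loci identical copies of one locus → every replicate equals
        the point estimate."""
        base = make_random_dataset(rng, n_pops=2, n_per_pop=20, n_loci=1)
        calls = np.repeat(base.calls, 4, axis=1)
        ds = GenotypeDataset(
            base.individuals, base.populations,
            [LocusMeta(f"L{l}", motif_length=1) for l in range(4)], calls,
        )
        f = allele_frequencies(ds)
        point = delta_mu2(f)
        reps = bootstrap_distance(f, "dmu2", B=8, seed=0)
        for m in reps.matrices:
            np.testing.assert_allclose(m.values, point.values, atol=1e-12)

    def test_invalid_b_rejected(self, rng):
        f = allele_frequencies(make_random_dataset(rng))
        with pytest.raises(ValueError, match="B"):
            bootstrap_distance(f, "Ds", B=0)
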