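import itertools

import numpy as np
import pytest

from msatpop.io import GenotypeDataset, LocusMeta, allele_frequencies
from msatpop.simulate import simulate_admixture
from msatpop.structure import (
    ClusterRun,
    admixture_gibbs,
    align_runs,
    dapc,
    evanno_delta_k,
)


def disjoint_two_cluster_ds(seed=1, n=30, L=8):
    P = np.zeros((2, L, 4))
    P[0, :, :2] = 0.5
    P[1, :, 2:] = 0.5
    return simulate_admixture(2, L, [n, n], allele_profiles=P, alpha=0.0, seed=seed)


class TestGibbs:
    def test_k1_forced_assignment(self, rng):
        ds, _ = disjoint_two_cluster_ds()
        run = admixture_gibbs(ds, 1, burn_in=50, iterations=300, thin=5, seed=0)
        np.testing.assert_allclose(run.Q, 1.0)
        assert np.isfinite(run.L_hat)

    def test_determinism(self):
        ds, _ = disjoint_two_cluster_ds()
        kw = dict(burn_in=50, iterations=300, thin=5, seed=123)
        r1 = admixture_gibbs(ds, 2, **kw)
        r2 = admixture_gibbs(ds, 2, **kw)
        np.testing.assert_array_equal(r1.Q, r2.Q)
        np.testing.assert_array_equal(r1.lnL_trace, r2.lnL_trace)

    def test_q_rows_simplex(self):
        ds, _ = disjoint_two_cluster_ds()
        run = admixture_gibbs(ds, 3, burn_in=50, iterations=300, thin=5, seed=3)
        np.testing.assert_allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            run.P.sum(axis=2)[:, : run.P.shape[1]], 1.0, atol=1e-9
        )

    def test_recovers_disjoint_clusters(self):
        ds, Q_true = disjoint_two_cluster_ds(n=40, L=10)
        run = admixture_gibbs(ds, 2, alpha=0.1, burn_in=200, iterations=1200,
                              thin=5, seed=7)
        ref = ClusterRun(
            K=2, Q=Q_true, P=run.P, allele_lists=run.allele_lists,
            lnL_trace=run.lnL_trace, L_hat=run.L_hat, alpha=0.1, lam=1.0,
            burn_in=0, iterations=1, thin=1, seed=None,
        )
        aligned = align_runs(ref, run)
        own = aligned.Q[np.arange(len(Q_true)), Q_true.argmax(axis=1)]
        assert own.min() >= 0.95

    def test_k1_conjugate_posterior(self):
        """With K=1 the stationary distribution of P is the conjugate
        Dirichlet posterior: mean (λ + counts)/(Σλ + Σcounts)."""
        rng = np.random.default_rng(11)
        calls = rng.choice([10, 12, 14], size=(40, 1, 2), p=[0.5, 0.3, 0.2])
        ds = GenotypeDataset(
            [f"i{k}" for k in range(40)], ["P"] * 40,
            [LocusMeta("L", motif_length=1)], calls,
        )
        lam = 1.0
        run = admixture_gibbs(ds, 1, lam=lam, burn_in=100, iterations=50100,
                              thin=5, seed=5)
        lf = allele_frequencies(ds).loci[0]
        counts = lf.pooled_counts().astype(float)
        expected = (lam + counts) / (lam * len(counts) + counts.sum())
        # with K=1 the allele counts are fixed, so each recorded P is an
        # iid draw from the exact Dirichlet posterior: MC SE = sd/sqrt(n)
        tot = lam * len(counts) + counts.sum()
        post_sd = np.sqrt(expected * (1 - expected) / (tot + 1))
        n_rec = len(run.lnL_trace)
        np.testing.assert_array_less(
            np.abs(run.P[0, 0, : len(counts)] - expected),
            3 * post_sd / np.sqrt(n_rec),
        )

    def test_invalid_chain_settings(self):
        ds, _ = disjoint_two_cluster_ds()
        with pytest.raises(ValueError):
            admixture_gibbs(ds, 2, burn_in=100, iterations=100)
        with pytest.raises(ValueError):
            admixture_gibbs(ds, 0)


class TestEvanno:
    @staticmethod
    def fake_runs(means, sd=10.0, reps=3):
        runs = []
        offsets = np.array([-1.0, 0.0, 1.0]) * sd  # sample SD exactly `sd`
        for k, m in means.items():
            for off in offsets[:reps]:
                runs.append(
                    ClusterRun(
                        K=k, Q=np.ones((1, k)) / k, P=np.ones((k, 1, 1)),
                        allele_lists=[], lnL_trace=np.array([m + off]),
                        L_hat=m + off, alpha=1, lam=1, burn_in=0,
                        iterations=1, thin=1, seed=None,
                    )
                )
        return runs

    def test_hand_example(self):
        """Means (−5000, −4000, −3900, −3890): |L''| at K=2 is 900,
        dominating → selected K = 2."""
        runs = self.fake_runs({1: -5000, 2: -4000, 3: -3900, 4: -3890})
        ev = evanno_delta_k(runs)
        assert ev.table.loc[2, "Lpp"] == pytest.approx(900.0)
        assert ev.selected_k == 2

    def test_linear_l_no_curvature(self):
        runs = self.fake_runs({k: -5000 + 100 * k for k in range(1, 5)})
        ev = evanno_delta_k(runs)
        interior = ev.table["Lpp"].dropna()
        assert np.allclose(interior, 0.0, atol=1e-9)

    def test_replicate_requirement(self):
        runs = self.fake_runs({1: -10, 2: -5, 3: -4}, reps=2)
        with pytest.raises(ValueError, match="replicate"):
            evanno_delta_k(runs)

    def test_nonconsecutive_k_rejected(self):
        runs = self.fake_runs({1: -10, 3: -4})
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k(runs)


class TestAlign:
    @staticmethod
    def run_with_q(Q):
        K = Q.shape[1]
        return ClusterRun(
            K=K, Q=Q, P=np.ones((K, 1, 1)), allele_lists=[],
            lnL_trace=np.array([0.0]), L_hat=0.0, alpha=1, lam=1,
            burn_in=0, iterations=1, thin=1, seed=None,
        )

    def test_recovers_column_swap(self, rng):
        Q = rng.dirichlet(np.ones(3), size=20)
        ref = self.run_with_q(Q)
        other = self.run_with_q(Q[:, [2, 0, 1]])
        aligned = align_runs(ref, other)
        np.testing.assert_allclose(aligned.Q, Q)

    def test_identity(self, rng):
        Q = rng.dirichlet(np.ones(2), size=10)
        aligned = align_runs(self.run_with_q(Q), self.run_with_q(Q))
        np.testing.assert_allclose(aligned.Q, Q)

    def test_matches_exhaustive_best(self, rng):
        """Assignment solution equals the best of all K! permutations."""
        for K in (2, 3, 4):
            Qr = rng.dirichlet(np.ones(K), size=15)
            Qo = rng.dirichlet(np.ones(K), size=15)
            aligned = align_runs(self.run_with_q(Qr), self.run_with_q(Qo))
            got = float(np.sum(Qr * aligned.Q))
            best = max(
                float(np.sum(Qr * Qo[:, list(perm)]))
                for perm in itertools.permutations(range(K))
            )
            assert got == pytest.approx(best)

    def test_label_switch_leaves_l_hat(self, rng):
        Q = rng.dirichlet(np.ones(3), size=12)
        other = self.run_with_q(Q[:, [1, 2, 0]])
        assert align_runs(self.run_with_q(Q), other).L_hat == other.L_hat

    def test_k_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="K"):
            align_runs(
                self.run_with_q(rng.dirichlet(np.ones(2), size=5)),
                self.run_with_q(rng.dirichlet(np.ones(3), size=5)),
            )


class TestDapc:
    def test_disjoint_groups_fully_separate(self):
        ds, _ = disjoint_two_cluster_ds(n=25, L=8)
        res = dapc(ds)
        x = res.discriminant_coords[:, 0]
        g = np.asarray(res.group_of)
        a, b = x[g == "pop1"], x[g == "pop2"]
        assert a.max() < b.min() or b.max() < a.min()

    def test_homogeneous_population_no_structure(self, rng):
        """Random group labels on one homogeneous population: observed
        between-group separation is within the permutation null."""
        calls = rng.choice([10, 12, 14, 16], size=(60, 6, 2))
        groups = ["g1"] * 30 + ["g2"] * 30
        ds = GenotypeDataset(
            [f"i{k}" for k in range(60)], groups,
            [LocusMeta(f"L{l}", motif_length=1) for l in range(6)], calls,
        )

        def separation(labels):
            res = dapc(ds, groups=list(labels), n_pcs=10)
            x = res.discriminant_coords[:, 0]
            la = np.asarray(labels)
            return abs(x[la == "g1"].mean() - x[la == "g2"].mean()) / (x.std() + 1e-12)

        obs = separation(groups)
        null = [separation(rng.permutation(groups)) for _ in range(30)]
        assert obs <= np.quantile(null, 0.99) * 1.5

    def test_lossless_reduction_axis_count(self):
        ds, _ = disjoint_two_cluster_ds(n=20, L=6)
        res = dapc(ds, n_pcs=10_000)  # clipped to full rank
        assert res.discriminant_coords.shape[1] == 1  # groups − 1

    def test_small_group_rejected(self, rng):
        ds, _ = disjoint_two_cluster_ds(n=10)
        groups = ["a"] + ["b"] * (ds.n_individuals - 1)
        with pytest.raises(ValueError, match="< 2"):
            dapc(ds, groups=groups)
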