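import numpy as np
import pytest

from msatpop.distances import BootstrapReplicates
from msatpop.matrix import PairwiseMatrix
from msatpop.tree import UnrootedTree, bootstrap_supports, neighbor_joining, to_newick


def random_additive_matrix(rng, n_leaves):
    """Random binary tree with positive branches and its exact path-length
    matrix — the brute-force additivity oracle."""
    tree = UnrootedTree()
    labels = [f"T{i}" for i in range(n_leaves)]
    for i in range(3):
        tree.labels[i] = labels[i]
    center = n_leaves  # first internal node id
    next_id = n_leaves + 1
    for i in range(3):
        tree._add_edge(i, center, float(rng.uniform(0.1, 2.0)))
    for i in range(3, n_leaves):
        # split a random existing edge with a new internal node
        edges = [(u, v) for u in tree.adj for v in tree.adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = next_id
        next_id += 1
        length = tree.adj[u].pop(v)
        tree.adj[v].pop(u)
        split = float(rng.uniform(0.2, 0.8))
        tree._add_edge(u, w, length * split)
        tree._add_edge(w, v, length * (1 - split))
        tree.labels[i] = labels[i]
        tree._add_edge(i, w, float(rng.uniform(0.1, 2.0)))
    return tree, tree.path_lengths()


class TestNeighborJoining:
    def test_four_taxon_additive(self):
        """d(A,B)=d(C,D)=2, cross pairs 3 → split AB|CD, all branches 1."""
        d = PairwiseMatrix(
            list("ABCD"),
            np.array(
                [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
            ),
        )
        t = neighbor_joining(d)
        bips = set(t.bipartitions().values())
        assert bips == {frozenset({"C", "D"})} or bips == {frozenset({"A", "B"})}
        assert t.path_lengths().allclose(d, atol=1e-9)
        assert t.total_length() == pytest.approx(5.0)

    def test_three_taxon_closed_form(self):
        d = PairwiseMatrix(
            list("ABC"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        )
        t = neighbor_joining(d)
        # L_A = (d_AB + d_AC − d_BC)/2 = 1, L_B = 2, L_C = 3
        lengths = {t.labels[leaf]: list(t.adj[leaf].values())[0] for leaf in t.leaves}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    @pytest.mark.parametrize("n_leaves", [4, 6, 8])
    def test_recovers_generating_topology(self, rng, n_leaves):
        for rep in range(10):
            true_tree, d = random_additive_matrix(rng, n_leaves)
            inferred = neighbor_joining(d)
            assert set(inferred.bipartitions().values()) == set(
                true_tree.bipartitions().values()
            )
            assert inferred.path_lengths().allclose(d, atol=1e-9)

    def test_total_length_invariant_to_label_order(self, rng):
        _, d = random_additive_matrix(rng, 7)
        perm = rng.permutation(d.n)
        d2 = PairwiseMatrix(
            [d.labels[i] for i in perm], d.values[np.ix_(perm, perm)], d.statistic
        )
        assert neighbor_joining(d2).total_length() == pytest.approx(
            neighbor_joining(d).total_length()
        )

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(PairwiseMatrix(["A", "B"], np.zeros((2, 2))))

    def test_nan_rejected(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            neighbor_joining(PairwiseMatrix(list("ABC"), v))

    def test_agrees_with_scikit_bio(self, rng):
        """Independent cross-check: same topology as scikit-bio's NJ on a
        noisy (non-additive) matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        _, d = random_additive_matrix(rng, 8)
        noisy = d.values + rng.uniform(0, 0.05, d.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        pm = PairwiseMatrix(d.labels, noisy)
        ours = neighbor_joining(pm)
        theirs = skbio_nj(skbio.DistanceMatrix(noisy, ids=d.labels))
        their_bips = {
            frozenset(t.name for t in clade.tips())
            for clade in theirs.non_tips(include_self=False)
        }
        ref = min(pm.labels)
        full = set(pm.labels)
        canon = {
            frozenset(full - b) if ref in b else b
            for b in their_bips
            if 2 <= len(b) <= len(full) - 2
        }
        assert set(ours.bipartitions().values()) <= canon | {
            frozenset(full - b) for b in canon
        }
        assert len(set(ours.bipartitions().values())) == len(canon)


class TestBootstrapSupports:
    def test_identical_replicates_full_support(self, rng):
        _, d = random_additive_matrix(rng, 6)
        reps = BootstrapReplicates("Ds", 5, 0, np.zeros((5, 1), int), [d] * 5)
        t = bootstrap_supports(neighbor_joining(d), reps)
        assert t.supports and all(s == 100.0 for s in t.supports.values())

    def test_half_support(self):
        """One agreeing and one topology-breaking replicate → 50%."""
        agree = PairwiseMatrix(
            list("ABCD"),
            np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float),
        )
        swap = PairwiseMatrix(  # AC|BD instead
            list("ABCD"),
            np.array([[0, 3, 2, 3], [3, 0, 3, 2], [2, 3, 0, 3], [3, 2, 3, 0]], float),
        )
        reps = BootstrapReplicates("Ds", 2, 0, np.zeros((2, 1), int), [agree, swap])
        t = bootstrap_supports(neighbor_joining(agree), reps)
        assert list(t.supports.values()) == [50.0]

    def test_label_mismatch_rejected(self, rng):
        _, d = random_additive_matrix(rng, 5)
        other = PairwiseMatrix(list("VWXYZ"), d.values)
        reps = BootstrapReplicates("Ds", 1, 0, np.zeros((1, 1), int), [other])
        with pytest.raises(ValueError, match="label"):
            bootstrap_supports(neighbor_joining(d), reps)

    def test_supports_invariant_to_leaf_order(self, rng):
        _, d = random_additive_matrix(rng, 6)
        reps_m = []
        for _ in range(4):
            noisy = d.values + rng.uniform(0, 0.3, d.values.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            reps_m.append(noisy)
        perm = rng.permutation(d.n)

        def supports(labels, values, rep_mats):
            pm = PairwiseMatrix(labels, values)
            reps = BootstrapReplicates(
                "Ds", len(rep_mats), 0, np.zeros((len(rep_mats), 1), int),
                [PairwiseMatrix(labels, m) for m in rep_mats],
            )
            t = bootstrap_supports(neighbor_joining(pm), reps)
            return {frozenset(t.bipartitions()[e]): s for e, s in t.supports.items()}

        s1 = supports(d.labels, d.values, reps_m)
        s2 = supports(
            [d.labels[i] for i in perm],
            d.values[np.ix_(perm, perm)],
            [m[np.ix_(perm, perm)] for m in reps_m],
        )
        assert s1 == s2


class TestNewick:
    def test_three_taxon_form(self):
        d = PairwiseMatrix(list("ABC"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        nwk = to_newick(neighbor_joining(d), decimals=1)
        assert nwk.startswith("(") and nwk.endswith(");")
        assert all(x in nwk for x in ("A:", "B:", "C:"))

    def test_round_trip_via_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        _, d = random_additive_matrix(rng, 7)
        t = neighbor_joining(d)
        nwk = to_newick(t, decimals=9)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in parsed.taxon_namespace}
        for i, a in enumerate(d.labels):
            for j, b in enumerate(d.labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        d.values[i, j], abs=1e-6
                    )

    def test_supports_after_closing_paren(self, rng):
        _, d = random_additive_matrix(rng, 6)
        reps = BootstrapReplicates("Ds", 2, 0, np.zeros((2, 1), int), [d, d])
        t = bootstrap_supports(neighbor_joining(d), reps)
        nwk = to_newick(t)
        assert ")100:" in nwk
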