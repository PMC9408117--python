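"""Neighbor-joining trees, bootstrap supports, and Newick serialization.

Saitou–Nei neighbor joining with the Studier–Keppler selection criterion
Q(i,j) = (n−2) d(i,j) − Σ_k d(i,k) − Σ_k d(j,k); consistent on additive
matrices.  Ties in the Q minimum break on the lowest (row, column) index
pair in canonical label order, so the topology is deterministic.  Negative
branch lengths are clamped to zero with the deficit transferred to the
sister branch of the same join (total path length preserved); raw values
are logged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distances import BootstrapReplicates
from .matrix import PairwiseMatrix

__all__ = ["UnrootedTree", "neighbor_joining", "bootstrap_supports", "to_newick"]

log = logging.getLogger(__name__)


@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map with labeled leaves.

    ``adj[u][v]`` is the length of edge (u, v); ``labels`` maps leaf node
    ids to population names; ``supports`` maps internal edges (frozenset of
    the two node ids) to bootstrap percentages in [0, 100].
    """

    adj: dict[int, dict[int, float]] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)
    supports: dict[frozenset, float] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return sorted(self.labels)

    @property
    def leaf_names(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def _add_edge(self, u: int, v: int, length: float) -> None:
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length

    def total_length(self) -> float:
        return sum(l for u in self.adj for l in self.adj[u].values()) / 2.0

    def path_lengths(self) -> PairwiseMatrix:
        """Leaf-to-leaf path-length metric of the tree."""
        leaves = self.leaves
        names = [self.labels[i] for i in leaves]
        n = len(leaves)
        m = np.zeros((n, n))
        for a, src in enumerate(leaves):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, l in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + l
                        stack.append(v)
            for b, dst in enumerate(leaves):
                m[a, b] = dist[dst]
        np.fill_diagonal(m, 0.0)
        return PairwiseMatrix(names, m, "path")

    def _side(self, u: int, v: int) -> frozenset:
        """Leaf labels on the v-side of edge (u, v)."""
        seen = {u, v}
        out = []
        stack = [v]
        while stack:
            x = stack.pop()
            if x in self.labels:
                out.append(self.labels[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self) -> dict[frozenset, frozenset]:
        """Canonical nontrivial leaf bipartitions, keyed edge → side.

        The canonical side is the one NOT containing the alphabetically
        first leaf label, so bipartitions compare across trees that share a
        leaf set.
        """
        ref = min(self.labels.values())
        out = {}
        for u in self.adj:
            for v in self.adj[u]:
                if u < v and u not in self.labels and v not in self.labels:
                    side = self._side(u, v)
                    if ref in side:
                        side = frozenset(set(self.labels.values()) - side)
                    if len(side) >= 2 and len(self.labels) - len(side) >= 2:
                        out[frozenset((u, v))] = side
        return out


def neighbor_joining(d: PairwiseMatrix) -> UnrootedTree:
    """Build the NJ tree for a symmetric finite distance matrix (n ≥ 3)."""
    n = d.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(d.values).all():
        raise ValueError("distance matrix has non-finite entries")
    # canonical order: the label order of the input matrix
    order = np.argsort(np.arange(n), kind="stable")
    tree = UnrootedTree()
    for i, lab in enumerate(d.labels):
        tree.labels[i] = lab
    active = list(range(n))          # node ids, in creation/canonical order
    D = {(i, j): float(d.values[i, j]) for i in range(n) for j in range(n)}
    next_id = n

    def dist(i, j):
        return 0.0 if i == j else D[(i, j)] if (i, j) in D else D[(j, i)]

    while len(active) > 3:
        m = len(active)
        row_sums = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = dist(i, j)
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj, d.labels, i, j)
        u = next_id
        next_id += 1
        tree._add_edge(i, u, li)
        tree._add_edge(j, u, lj)
        for k in active:
            if k not in (i, j):
                D[(u, k)] = 0.5 * (dist(i, k) + dist(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    # final star join of the last three nodes
    i, j, k = active
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    u = next_id
    li = (dij + dik - djk) / 2
    lj = (dij + djk - dik) / 2
    lk = (dik + djk - dij) / 2
    for node, raw in ((i, li), (j, lj), (k, lk)):
        if raw < 0:
            log.debug("negative terminal branch %.4g clamped to 0", raw)
    tree._add_edge(i, u, max(li, 0.0))
    tree._add_edge(j, u, max(lj, 0.0))
    tree._add_edge(k, u, max(lk, 0.0))
    return tree


def _clamp_pair(li: float, lj: float, labels, i, j) -> tuple[float, float]:
    if li < 0:
        log.debug("branch to node %s: raw %.4g clamped to 0", i, li)
        lj += li
        li = 0.0
    if lj < 0:
        log.debug("branch to node %s: raw %.4g clamped to 0", j, lj)
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def bootstrap_supports(
    point_tree: UnrootedTree, replicates: BootstrapReplicates
) -> UnrootedTree:
    """Annotate internal edges with bootstrap support percentages.

    Support of an edge = 100 × fraction of replicate NJ trees whose
    bipartition set contains the edge's leaf bipartition.
    """
    point_bips = point_tree.bipartitions()
    leafset = set(point_tree.labels.values())
    counts = {edge: 0 for edge in point_bips}
    for pm in replicates.matrices:
        if set(pm.labels) != leafset:
            raise ValueError("replicate label set differs from the point tree")
        rep_bips = set(neighbor_joining(pm).bipartitions().values())
        for edge, bip in point_bips.items():
            if bip in rep_bips:
                counts[edge] += 1
    point_tree.supports = {
        edge: 100.0 * c / replicates.B for edge, c in counts.items()
    }
    return point_tree


def to_newick(tree: UnrootedTree, decimals: int = 6) -> str:
    """Newick text with branch lengths and integer supports as internal
    node labels (written after the closing parenthesis)."""
    # root at an internal node: the highest id (the last join)
    internal = [u for u in tree.adj if u not in tree.labels]
    root = max(internal) if internal else tree.leaves[0]

    def fmt(u: int, parent: int | None, length: float | None) -> str:
        children = [v for v in tree.adj[u] if v != parent]
        if u in tree.labels:
            body = tree.labels[u]
        else:
            body = "(" + ",".join(fmt(v, u, tree.adj[u][v]) for v in sorted(children)) + ")"
            if parent is not None:
                sup = tree.supports.get(frozenset((u, parent)))
                if sup is not None:
                    body += f"{round(sup):d}"
        if length is not None:
            body += f":{length:.{decimals}f}"
        return body

    return fmt(root, None, None) + ";"
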