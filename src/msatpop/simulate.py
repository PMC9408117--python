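"""Forward-time Wright–Fisher simulation of microsatellites under the SMM.

The engine simulates diploid populations of constant size N_e with
discrete non-overlapping generations, random mating (selfing allowed) and
single-step stepwise mutation: each transmitted allele copy mutates with
probability β per generation, moving ±1 repeat unit with equal
probability.  Populations live on a rooted split tree: a single ancestral
population is burned in to mutation–drift equilibrium, then copied into
its descendants at each split time.  Optional symmetric migration
exchanges individuals between contemporaneous populations every
generation.

Allele codes in simulated datasets are repeat counts (convertible to
fragment sizes in bp through a per-locus offset and motif length).

Under this model the expected (δµ)² between two populations that split τ
generations ago is 2βτ once the ancestral population has equilibrated —
the closed form the divergence-dating module inverts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeDataset, LocusMeta

__all__ = [
    "SplitNode",
    "SimConfig",
    "mutate_smm",
    "simulate_smm",
    "simulate_admixture",
    "STUDY_BREEDS",
    "make_study_fixture",
]

log = logging.getLogger(__name__)


@dataclass
class SplitNode:
    """Internal node of a rooted population-split tree.

    ``time`` is the split time in generations before present; children are
    further :class:`SplitNode` instances or terminal population labels.
    Times must strictly decrease toward the present along any path.
    """

    time: float
    children: list  # SplitNode | str

    def leaves(self) -> list[str]:
        out = []
        for c in self.children:
            out.extend(c.leaves() if isinstance(c, SplitNode) else [c])
        return out

    def validate(self, parent_time: float = np.inf) -> None:
        if not self.time < parent_time:
            raise ValueError(
                f"split time {self.time} does not decrease below parent {parent_time}"
            )
        if self.time < 0:
            raise ValueError("split times must be >= 0")
        for c in self.children:
            if isinstance(c, SplitNode):
                c.validate(self.time)


@dataclass
class SimConfig:
    """Configuration of one forward SMM simulation."""

    split_tree: SplitNode | str
    n_e: int = 500
    beta: float = 1e-3
    L: int = 20
    motif_length: int = 2
    founder_allele: int = 20
    sample_sizes: "dict[str, int] | int" = 30
    migration: float | None = None      # symmetric per-pair rate among extant pops
    burn_in: int | None = None          # pre-root generations; default 6 * n_e
    size_bounds: tuple[int, int] | None = None  # reflecting repeat-count bounds
    seed: int | None = None

    def sample_size(self, pop: str) -> int:
        if isinstance(self.sample_sizes, dict):
            return int(self.sample_sizes[pop])
        return int(self.sample_sizes)

    def validate(self) -> None:
        tree = self.split_tree
        if isinstance(tree, SplitNode):
            tree.validate()
            leaves = tree.leaves()
        else:
            leaves = [tree]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate population labels in split tree")
        for p in leaves:
            if self.sample_size(p) > self.n_e:
                raise ValueError(f"sample size for {p} exceeds N_e={self.n_e}")
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must be in [0, 1]")
        if self.migration is not None and not (0 <= self.migration <= 1):
            raise ValueError("migration rate must be in [0, 1]")


def mutate_smm(
    alleles: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    bounds: tuple[int, int] | None = None,
) -> tuple[np.ndarray, int]:
    """Apply single-step SMM mutation; returns (mutated copy, event count).

    Each entry mutates with probability ``beta`` by ±1 repeat with equal
    probability; optional reflecting bounds keep sizes inside a window.
    """
    mask = rng.random(alleles.shape) < beta
    steps = rng.integers(0, 2, size=alleles.shape) * 2 - 1
    out = alleles + mask * steps
    if bounds is not None:
        lo, hi = bounds
        out = np.where(out < lo, 2 * lo - out, out)
        out = np.where(out > hi, 2 * hi - out, out)
    return out, int(mask.sum())


class _Engine:
    """Single-timeline forward simulator over a split tree."""

    def __init__(self, cfg: SimConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.mutations = 0

    def _reproduce(self, state: np.ndarray) -> np.ndarray:
        """One Wright–Fisher generation with mutation.  state: (N, 2, L)."""
        cfg = self.cfg
        N, _, L = state.shape
        parents = self.rng.integers(0, N, size=(N, 2))
        which = self.rng.integers(0, 2, size=(N, 2, L))
        gametes = state[parents[:, :, None], which, np.arange(L)[None, None, :]]
        out, n_mut = mutate_smm(gametes, cfg.beta, self.rng, cfg.size_bounds)
        self.mutations += n_mut
        return out

    def _migrate(self, pops: dict[str, np.ndarray]) -> None:
        m = self.cfg.migration
        if not m or len(pops) < 2:
            return
        names = sorted(pops)
        for a_i in range(len(names)):
            for b_i in range(a_i + 1, len(names)):
                a, b = names[a_i], names[b_i]
                na, nb = len(pops[a]), len(pops[b])
                ka = self.rng.binomial(na, m)
                kb = self.rng.binomial(nb, m)
                k = min(ka, kb)   # swap equal numbers to keep sizes constant
                if k == 0:
                    continue
                ia = self.rng.choice(na, size=k, replace=False)
                ib = self.rng.choice(nb, size=k, replace=False)
                pops[a][ia], pops[b][ib] = pops[b][ib].copy(), pops[a][ia].copy()

    def run(self) -> dict[str, np.ndarray]:
        cfg = self.cfg
        burn = cfg.burn_in if cfg.burn_in is not None else 6 * cfg.n_e
        founder = np.full((cfg.n_e, 2, cfg.L), cfg.founder_allele, dtype=np.int64)
        tree = cfg.split_tree
        root_time = tree.time if isinstance(tree, SplitNode) else 0.0

        # event queue: (time, node) with times strictly decreasing
        root_label = "__root__"
        pops: dict[str, np.ndarray] = {root_label: founder}
        pending: dict[str, SplitNode] = {}
        if isinstance(tree, SplitNode):
            pending[root_label] = tree
        else:
            pops = {tree: founder}

        for _ in range(int(burn)):
            pops = {k: self._reproduce(v) for k, v in pops.items()}

        t = root_time
        while t > 0 or pending:
            # split every pending node whose time is reached
            due = [k for k, node in pending.items() if node.time >= t]
            for k in due:
                node = pending.pop(k)
                state = pops.pop(k)
                for ci, child in enumerate(node.children):
                    label = child if isinstance(child, str) else f"__{id(child)}__"
                    pops[label] = state.copy()
                    if isinstance(child, SplitNode):
                        pending[label] = child
            if t <= 0:
                break
            pops = {k: self._reproduce(v) for k, v in pops.items()}
            self._migrate(pops)
            t -= 1
        return pops


def simulate_smm(cfg: SimConfig) -> GenotypeDataset:
    """Run the forward SMM simulation and sample terminal populations.

    Terminal samples are drawn without replacement; the result is a
    validated :class:`GenotypeDataset` with repeat-count allele codes and
    loci named ``L01..``.
    """
    engine = _Engine(cfg)
    pops = engine.run()
    rng = engine.rng
    tree = cfg.split_tree
    order = tree.leaves() if isinstance(tree, SplitNode) else [tree]
    loci = [
        LocusMeta(f"L{l + 1:02d}", motif_length=cfg.motif_length) for l in range(cfg.L)
    ]
    inds, labels, rows = [], [], []
    for pop in order:
        state = pops[pop]
        take = rng.choice(len(state), size=cfg.sample_size(pop), replace=False)
        for r, i in enumerate(sorted(take)):
            inds.append(f"{pop}_{r + 1:03d}")
            labels.append(pop)
            rows.append(state[i].T)   # engine state is (copy, locus)
    calls = np.stack(rows) if rows else np.empty((0, cfg.L, 2), dtype=np.int64)
    return GenotypeDataset(inds, labels, loci, calls)


# ---------------------------------------------------------------------------
# admixture-model generator (frequency level)
# ---------------------------------------------------------------------------


def simulate_admixture(
    K: int,
    L: int,
    sample_sizes: list[int] | int,
    allele_profiles: np.ndarray | None = None,
    n_alleles: int = 5,
    alpha: float = 0.1,
    seed: int | None = None,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Draw genotypes from the admixture model itself; returns (ds, true Q).

    Each individual's ancestry Q_i ~ Dirichlet(α·1_K); every allele copy
    first draws its cluster of origin from Q_i, then its allele from that
    cluster's frequency profile.  ``allele_profiles`` is (K, L, A); when
    omitted, profiles are Dirichlet(1) draws over ``n_alleles`` alleles.
    Individuals are grouped into populations pop1..popG (one per entry of
    ``sample_sizes``).  ``alpha=0`` is the no-admixture limit: each
    individual is a pure member of its population's cluster (requires as
    many populations as clusters).
    """
    rng = np.random.default_rng(seed)
    if allele_profiles is None:
        allele_profiles = rng.dirichlet(np.ones(n_alleles), size=(K, L))
    P = np.asarray(allele_profiles, dtype=float)
    if P.shape[0] != K or P.shape[1] != L:
        raise ValueError(f"allele_profiles shape {P.shape} incompatible with K={K}, L={L}")
    A = P.shape[2]
    sizes = [sample_sizes] if isinstance(sample_sizes, int) else list(sample_sizes)
    N = sum(sizes)
    if K == 1:
        Q = np.ones((N, 1))
    elif alpha == 0:
        if len(sizes) != K:
            raise ValueError("alpha=0 (pure ancestry) needs one population per cluster")
        Q = np.zeros((N, K))
        Q[np.arange(N), np.repeat(np.arange(K), sizes)] = 1.0
    else:
        Q = rng.dirichlet(np.full(K, alpha), size=N)
    calls = np.zeros((N, L, 2), dtype=np.int64)
    for i in range(N):
        z = rng.choice(K, size=(L, 2), p=Q[i]) if K > 1 else np.zeros((L, 2), int)
        for c in (0, 1):
            for l in range(L):
                # allele codes 10.. so they are valid microsatellite sizes
                calls[i, l, c] = 10 + rng.choice(A, p=P[z[l, c], l])
    inds, labels = [], []
    g = 0
    for gi, sz in enumerate(sizes):
        for r in range(sz):
            inds.append(f"pop{gi + 1}_{r + 1:03d}")
            labels.append(f"pop{gi + 1}")
            g += 1
    loci = [LocusMeta(f"L{l + 1:02d}", motif_length=1) for l in range(L)]
    return GenotypeDataset(inds, labels, loci, calls), Q


# ---------------------------------------------------------------------------
# study-shaped fixture
# ---------------------------------------------------------------------------

#: 11 Mediterranean breeds with the study's per-breed sample sizes
STUDY_BREEDS: dict[str, int] = {
    "BAR": 64, "QFO": 41, "CRO": 30, "DM": 28, "SS": 45, "NTH": 41,
    "ALP": 250, "BRO": 186, "FOZ": 118, "LAM": 141, "APP": 31,
}


def study_split_tree() -> SplitNode:
    """11-breed split topology with deep, intermediate and recent phases.

    Times (generations) echo the three divergence phases the divergence
    dating of the real panel points to: a deep split separating the
    D'man + Venetian lineage from the Appenninica + North-Maghreb lineage,
    intermediate splits within each side, and recent breed formations.
    """
    venetian = SplitNode(700, [
        SplitNode(400, ["LAM", "FOZ"]),
        SplitNode(420, ["ALP", "BRO"]),
    ])
    north_branch = SplitNode(2400, ["DM", venetian])
    recent_maghreb = SplitNode(250, [SplitNode(120, ["QFO", "CRO"]), "NTH"])
    south_branch = SplitNode(1700, [
        "BAR",
        SplitNode(900, [SplitNode(350, ["APP", "SS"]), recent_maghreb]),
    ])
    return SplitNode(2750, [south_branch, north_branch])


def make_study_fixture(
    seed: int | None = 0,
    n_e: int = 400,
    beta: float = 8e-3,
    burn_in: int = 1500,
) -> GenotypeDataset:
    """Simulate a dataset with the study's shape: 975 individuals in 11
    breeds typed at 17 microsatellites.

    Per-locus metadata (names, motif, fragment-size windows) comes from
    the packaged marker panel; repeat counts are mapped into each locus's
    bp window.  Mutation rate and effective size are tuned so pooled
    per-locus allele counts land in the panel's observed 16–38 range for
    most loci.
    """
    from .study import load_study_loci

    panel = load_study_loci()
    cfg = SimConfig(
        split_tree=study_split_tree(),
        n_e=n_e,
        beta=beta,
        L=len(panel),
        motif_length=2,
        founder_allele=30,
        sample_sizes=dict(STUDY_BREEDS),
        burn_in=burn_in,
        seed=seed,
    )
    ds = simulate_smm(cfg)
    # map repeat counts into each locus's bp window: bp = offset + 2 * repeat
    loci = []
    calls = ds.calls.copy()
    for l, row in enumerate(panel.itertuples()):
        mid = (row.size_min + row.size_max) // 2
        offset = mid - 2 * cfg.founder_allele
        obs = calls[:, l, :] != -1
        calls[:, l, :][obs] = offset + 2 * calls[:, l, :][obs]
        loci.append(
            LocusMeta(row.locus, motif_length=2, chromosome=str(row.chromosome))
        )
    return GenotypeDataset(ds.individuals, ds.populations, loci, calls)
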