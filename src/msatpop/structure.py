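"""Admixture-model clustering, ΔK model selection, and DAPC.

The clustering is a Gibbs sampler for the no-admixture-prior-free
admixture model: each individual i carries ancestry proportions Q_i over K
clusters; each allele copy draws a cluster of origin Z ∝ q_{i,k} p_{k,l,a}
and then its allele from the cluster's frequency profile.  Conditionals
are conjugate: P_{k,l} ~ Dirichlet(λ + assigned allele counts) and
Q_i ~ Dirichlet(α + assigned copy counts).  The model log-likelihood
ln P(X|Q,P) is recorded on a thinned post-burn-in trace and summarized as
L̂ = mean(lnL) − var(lnL)/2, the usual harmonic-style estimate of
ln P(X|K) used for ΔK model selection.

ΔK (Evanno's criterion) is |L(K+1) − 2L(K) + L(K−1)| / SD(L(K)) over
replicate runs; the K maximizing ΔK is selected.

DAPC encodes individuals as centered allele-dosage vectors, reduces by
PCA, then fits linear discriminant axes on the group labels.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import GenotypeDataset, MISSING, allele_frequencies

__all__ = [
    "ClusterRun",
    "EvannoTable",
    "DapcResult",
    "admixture_gibbs",
    "evanno_delta_k",
    "align_runs",
    "dapc",
    "dosage_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class ClusterRun:
    """One MCMC run of the admixture model at a fixed K."""

    K: int
    Q: np.ndarray                    # (N, K) posterior-mean admixture
    P: np.ndarray                    # (K, L, A_max) posterior-mean profiles
    allele_lists: list[np.ndarray]   # per locus, the allele codes backing P
    lnL_trace: np.ndarray            # recorded data log-likelihoods
    L_hat: float                     # estimated ln P(X|K)
    alpha: float
    lam: float
    burn_in: int
    iterations: int
    thin: int
    seed: int | None
    individuals: list[str] = field(default_factory=list)
    populations: list[str] = field(default_factory=list)

    def q_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Q, columns=[f"q_{k + 1}" for k in range(self.K)]
        )
        df.insert(0, "population", self.populations)
        df.insert(0, "individual", self.individuals)
        return df


def _encode(ds: GenotypeDataset):
    """Allele-index encoding: (N, L, 2) indices into per-locus allele lists."""
    freqs = allele_frequencies(ds)
    allele_lists = [lf.alleles for lf in freqs.loci]
    N, L = ds.n_individuals, ds.n_loci
    A_max = max((len(a) for a in allele_lists), default=1)
    AI = np.zeros((N, L, 2), dtype=np.int64)
    obs = np.ones((N, L, 2), dtype=bool)
    for l, alleles in enumerate(allele_lists):
        col = ds.calls[:, l, :]
        miss = col[:, 0] == MISSING
        obs[miss, l, :] = False
        lookup = {a: i for i, a in enumerate(alleles)}
        for c in (0, 1):
            AI[~miss, l, c] = [lookup[a] for a in col[~miss, c]]
    valid = np.zeros((L, A_max), dtype=bool)
    for l, alleles in enumerate(allele_lists):
        valid[l, : len(alleles)] = True
    return AI, obs, valid, allele_lists


def admixture_gibbs(
    ds: GenotypeDataset,
    K: int,
    alpha: float = 1.0,
    lam: float = 1.0,
    burn_in: int = 2000,
    iterations: int = 10000,
    thin: int = 10,
    seed: int | None = None,
) -> ClusterRun:
    """Gibbs sampler for the admixture model; reproducible under a seed.

    ``iterations`` is the total sweep count including ``burn_in``; the
    recorded trace takes every ``thin``-th sweep after burn-in.  Q and P
    are posterior means over the recorded sweeps.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not iterations > burn_in >= 0:
        raise ValueError("need iterations > burn_in >= 0")
    rng = np.random.default_rng(seed)
    AI, obs, valid, allele_lists = _encode(ds)
    N, L, _ = AI.shape
    A_max = valid.shape[1]
    n_distinct = len({tuple(row) for row in ds.calls.reshape(N, -1)})
    if K > n_distinct:
        log.warning("K=%d exceeds the %d distinct multilocus genotypes", K, n_distinct)

    lgrid = np.broadcast_to(np.arange(L)[None, :, None], (N, L, 2))
    Z = rng.integers(0, K, size=(N, L, 2))
    Q_sum = np.zeros((N, K))
    P_sum = np.zeros((K, L, A_max))
    lnLs: list[float] = []
    n_rec = 0

    for sweep in range(iterations):
        # P | Z: Dirichlet(λ + counts of alleles assigned to each cluster)
        counts = np.zeros((K, L, A_max))
        np.add.at(counts, (Z[obs], lgrid[obs], AI[obs]), 1.0)
        G = rng.gamma(lam + counts) * valid[None, :, :]
        P = G / G.sum(axis=2, keepdims=True)
        # Q | Z: Dirichlet(α + copies of each individual assigned to k)
        nik = np.zeros((N, K))
        igrid = np.broadcast_to(np.arange(N)[:, None, None], (N, L, 2))
        np.add.at(nik, (igrid[obs], Z[obs]), 1.0)
        GQ = rng.gamma(alpha + nik)
        Q = GQ / GQ.sum(axis=1, keepdims=True)
        # Z | Q, P: categorical ∝ q_{i,k} p_{k,l,a} per observed copy;
        # gather p_{k, l, a_(i,l,c)} -> (K, N, L, 2) then move K last
        pk = P[:, lgrid, AI]
        W = Q[:, None, None, :] * np.moveaxis(pk, 0, -1)
        W_sum = W.sum(axis=-1, keepdims=True)
        lnL = float(np.log(np.maximum(W_sum[obs], 1e-300)).sum())
        if not np.isfinite(lnL):
            raise FloatingPointError("non-finite data log-likelihood")
        cdf = np.cumsum(W / np.maximum(W_sum, 1e-300), axis=-1)
        u = rng.random(size=(N, L, 2, 1))
        Z = (u > cdf).sum(axis=-1)
        np.clip(Z, 0, K - 1, out=Z)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            Q_sum += Q
            P_sum += P
            lnLs.append(lnL)
            n_rec += 1

    trace = np.asarray(lnLs)
    L_hat = float(trace.mean() - trace.var(ddof=1) / 2.0) if len(trace) > 1 else float(
        trace.mean()
    )
    return ClusterRun(
        K=K,
        Q=Q_sum / n_rec,
        P=P_sum / n_rec,
        allele_lists=allele_lists,
        lnL_trace=trace,
        L_hat=L_hat,
        alpha=alpha,
        lam=lam,
        burn_in=burn_in,
        iterations=iterations,
        thin=thin,
        seed=seed,
        individuals=list(ds.individuals),
        populations=list(ds.populations),
    )


# ---------------------------------------------------------------------------
# ΔK model selection
# ---------------------------------------------------------------------------


@dataclass
class EvannoTable:
    table: pd.DataFrame
    selected_k: int


def evanno_delta_k(runs: list[ClusterRun]) -> EvannoTable:
    """ΔK model-selection table from replicate runs over consecutive K.

    Requires ≥3 replicate runs per K and a consecutive K range; ΔK is
    defined for interior K with SD > 0, and the K with the largest ΔK is
    flagged as selected.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.L_hat)
    ks = sorted(by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K values {ks} are not consecutive")
    if any(len(v) < 3 for v in by_k.values()):
        raise ValueError("need >= 3 replicate runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        lpp = (
            abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            if (k - 1 in mean and k + 1 in mean)
            else np.nan
        )
        dk = lpp / sd[k] if np.isfinite(lpp) and sd[k] > 0 else np.nan
        if np.isfinite(lpp) and sd[k] == 0:
            log.warning("SD(L) = 0 at K=%d: ΔK undefined there", k)
        rows.append(
            {"K": k, "mean_L": mean[k], "sd_L": sd[k], "Lp": lp, "Lpp": lpp, "deltaK": dk}
        )
    df = pd.DataFrame(rows).set_index("K")
    if df["deltaK"].notna().any():
        selected = int(df["deltaK"].idxmax())
    else:
        raise ValueError("ΔK undefined at every interior K")
    return EvannoTable(df, selected)


def align_runs(reference: ClusterRun, other: ClusterRun) -> ClusterRun:
    """Permute ``other``'s cluster labels to best match ``reference``.

    Maximizes Σ_i Σ_k Q_ref[i,k] Q_other[i,σ(k)] over label permutations σ
    (solved exactly as a linear assignment).  Returns a relabeled copy.
    """
    if reference.K != other.K:
        raise ValueError("runs have different K")
    M = reference.Q.T @ other.Q            # (K, K) agreement
    rows, cols = linear_sum_assignment(-M)
    perm = cols[np.argsort(rows)]
    out = ClusterRun(
        K=other.K,
        Q=other.Q[:, perm],
        P=other.P[perm],
        allele_lists=other.allele_lists,
        lnL_trace=other.lnL_trace,
        L_hat=other.L_hat,
        alpha=other.alpha,
        lam=other.lam,
        burn_in=other.burn_in,
        iterations=other.iterations,
        thin=other.thin,
        seed=other.seed,
        individuals=other.individuals,
        populations=other.populations,
    )
    return out


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


@dataclass
class DapcResult:
    n_pcs: int
    explained_variance_ratio: np.ndarray
    pc_coords: np.ndarray            # (N, n_pcs)
    discriminant_coords: np.ndarray  # (N, n_axes)
    axes: np.ndarray                 # (n_pcs, n_axes) discriminant loadings
    groups: list[str]
    group_of: list[str]


def dosage_matrix(ds: GenotypeDataset) -> tuple[np.ndarray, list[str]]:
    """Individuals × allele columns matrix of allele dosages (0/1/2).

    Missing genotypes are mean-imputed per column (the standard practice
    before PCA on genotype matrices).
    """
    freqs = allele_frequencies(ds)
    cols: list[str] = []
    blocks = []
    for l, lf in enumerate(freqs.loci):
        A = len(lf.alleles)
        block = np.zeros((ds.n_individuals, A))
        col = ds.calls[:, l, :]
        miss = col[:, 0] == MISSING
        lookup = {a: i for i, a in enumerate(lf.alleles)}
        rows = np.flatnonzero(~miss)
        for c in (0, 1):
            idx = np.array([lookup[a] for a in col[rows, c]], dtype=int)
            np.add.at(block, (rows, idx), 1.0)
        if miss.any():
            if (~miss).any():
                block[miss] = block[~miss].mean(axis=0)
            else:
                block[miss] = 0.0
        blocks.append(block)
        cols.extend(f"{lf.locus}.{a}" for a in lf.alleles)
    return np.hstack(blocks), cols


def dapc(
    ds: GenotypeDataset,
    groups: list[str] | None = None,
    n_pcs: int | str = "auto",
) -> DapcResult:
    """Discriminant analysis of principal components on allele dosages.

    ``n_pcs="auto"`` retains the smallest PC count explaining ≥90% of the
    dosage variance.  Discriminant axes are at most (number of groups − 1).
    """
    groups = list(groups) if groups is not None else list(ds.populations)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"group(s) with < 2 members: {list(counts[counts < 2].index)}"
        )
    X, _ = dosage_matrix(ds)
    X = X - X.mean(axis=0)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_rank, svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    if n_pcs == "auto":
        n_keep = int(np.searchsorted(np.cumsum(evr), 0.90) + 1)
    else:
        n_keep = min(int(n_pcs), max_rank)
    scores = scores[:, :n_keep]
    lda = LinearDiscriminantAnalysis(solver="svd")
    coords = lda.fit_transform(scores, groups)
    return DapcResult(
        n_pcs=n_keep,
        explained_variance_ratio=evr[:n_keep],
        pc_coords=scores,
        discriminant_coords=coords,
        axes=lda.scalings_[:, : coords.shape[1]],
        groups=labels,
        group_of=groups,
    )
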