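"""Between-population genetic distances and locus-bootstrap resampling.

Three allele-frequency statistics:

* molecular coancestry f_ij — probability that two random gene copies, one
  per population, are identical in state, averaged over loci;
* Nei's (1972) standard distance Ds = −ln(J_XY / √(J_X J_Y)) with the gene
  identities J averaged arithmetically over loci;
* Goldstein's (δµ)² — squared difference of population mean allele sizes
  averaged over loci, linear in divergence time under stepwise mutation
  (E[(δµ)²] = 2βτ).

Allele sizes for (δµ)² are expressed in repeat units; fragment sizes in bp
are converted through a per-locus offset and motif length
(:class:`AlleleSizeMap`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AlleleFrequencyTable
from .matrix import PairwiseMatrix

__all__ = [
    "AlleleSizeMap",
    "BootstrapReplicates",
    "coancestry_fij",
    "nei_ds",
    "delta_mu2",
    "bootstrap_distance",
    "DS_INF_SENTINEL",
]

log = logging.getLogger(__name__)

#: finite stand-in for infinite Ds when a tree needs finite input
DS_INF_SENTINEL = 1e9


@dataclass
class AlleleSizeMap:
    """Convert allele codes in bp to size scores in repeat units.

    score = (bp − offset) / motif_length per locus.  With no entry for a
    locus the codes are taken to be repeat counts already (identity map) —
    the convention of the simulator.
    """

    offsets: dict[str, int] = field(default_factory=dict)
    motif_lengths: dict[str, int] = field(default_factory=dict)

    def score(self, locus: str, alleles: np.ndarray) -> np.ndarray:
        alleles = np.asarray(alleles, dtype=float)
        if locus not in self.offsets:
            return alleles
        off = self.offsets[locus]
        motif = self.motif_lengths.get(locus, 1)
        s = (alleles - off) / motif
        if (s <= 0).any():
            bad = alleles[s <= 0][0]
            raise ValueError(
                f"allele {bad:g} at locus {locus!r} maps to non-positive size score"
            )
        return s


def _shared_loci(freqs: AlleleFrequencyTable, i: int, j: int) -> list[int]:
    return [
        k
        for k, lf in enumerate(freqs.loci)
        if not (lf.empty[i] or lf.empty[j])
    ]


def coancestry_fij(freqs: AlleleFrequencyTable) -> PairwiseMatrix:
    """Between-population molecular coancestry matrix.

    f_ij = (1/L) Σ_l Σ_a p_{l,i,a} p_{l,j,a}; the diagonal holds the
    within-population expected homozygosity (1/L) Σ_l Σ_a p².
    """
    pops = freqs.populations
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            loci = _shared_loci(freqs, i, j)
            if not loci:
                raise ValueError(f"no shared locus with data for {pops[i]}/{pops[j]}")
            vals = [
                float(np.sum(freqs.loci[k].freqs[i] * freqs.loci[k].freqs[j]))
                for k in loci
            ]
            m[i, j] = m[j, i] = float(np.mean(vals))
    return PairwiseMatrix(list(pops), m, "fij")


def nei_ds(freqs: AlleleFrequencyTable) -> PairwiseMatrix:
    """Nei's standard genetic distance matrix.

    J_X, J_Y and J_XY are arithmetic means over loci of Σp², Σ p_X p_Y;
    Ds = −ln(J_XY / √(J_X J_Y)).  Disjoint allele sets (J_XY = 0) yield a
    +inf sentinel with a warning.
    """
    pops = freqs.populations
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            loci = _shared_loci(freqs, i, j)
            if not loci:
                raise ValueError(f"no shared locus with data for {pops[i]}/{pops[j]}")
            jx = np.mean([np.sum(freqs.loci[k].freqs[i] ** 2) for k in loci])
            jy = np.mean([np.sum(freqs.loci[k].freqs[j] ** 2) for k in loci])
            jxy = np.mean(
                [np.sum(freqs.loci[k].freqs[i] * freqs.loci[k].freqs[j]) for k in loci]
            )
            if jxy == 0:
                log.warning("J_XY = 0 for %s/%s -> Ds = +inf", pops[i], pops[j])
                m[i, j] = m[j, i] = np.inf
            else:
                m[i, j] = m[j, i] = -np.log(jxy / np.sqrt(jx * jy))
    return PairwiseMatrix(list(pops), m, "Ds")


def _mean_sizes(
    freqs: AlleleFrequencyTable, sizes: AlleleSizeMap
) -> np.ndarray:
    """(L, P) matrix of population mean allele sizes (NaN where no data)."""
    L, P = len(freqs.loci), len(freqs.populations)
    mu = np.full((L, P), np.nan)
    for k, lf in enumerate(freqs.loci):
        s = sizes.score(lf.locus, lf.alleles)
        mu[k] = np.where(lf.empty, np.nan, lf.freqs @ s)
    return mu


def delta_mu2(
    freqs: AlleleFrequencyTable, sizes: AlleleSizeMap | None = None
) -> PairwiseMatrix:
    """Goldstein's (δµ)² distance matrix.

    D(X, Y) = (1/L) Σ_l (µ_{l,X} − µ_{l,Y})² with µ the mean allele size
    (in repeat units) of the population at that locus.
    """
    sizes = sizes or AlleleSizeMap()
    pops = freqs.populations
    mu = _mean_sizes(freqs, sizes)
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (mu[:, i] - mu[:, j]) ** 2
            d2 = d2[~np.isnan(d2)]
            if not len(d2):
                raise ValueError(f"no shared locus with data for {pops[i]}/{pops[j]}")
            m[i, j] = m[j, i] = float(d2.mean())
    return PairwiseMatrix(list(pops), m, "dmu2")


# ---------------------------------------------------------------------------
# locus bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapReplicates:
    """Locus-bootstrap replicate distance matrices.

    Each replicate resamples the L loci with replacement and recomputes the
    distance; deterministic for a fixed seed.
    """

    statistic: str
    B: int
    seed: int | None
    locus_indices: np.ndarray            # (B, L)
    matrices: list[PairwiseMatrix]


def _per_locus_ingredients(freqs, statistic, sizes):
    """Per-locus quantities from which each statistic is a simple pooling.

    Ds pools J-identities by arithmetic mean; (δµ)² averages per-locus
    squared mean-size gaps; F_ST is the ratio of summed variance components.
    """
    from .differentiation import wc_components  # local import, avoids cycle

    pops = freqs.populations
    n = len(pops)
    L = len(freqs.loci)
    if statistic == "dmu2":
        mu = _mean_sizes(freqs, sizes or AlleleSizeMap())

        def build(idx):
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d2 = (mu[idx, i] - mu[idx, j]) ** 2
                    m[i, j] = m[j, i] = float(np.nanmean(d2))
            return PairwiseMatrix(list(pops), m, "dmu2")

        return build
    if statistic == "Ds":
        jx = np.zeros((L, n))
        jxy = np.zeros((L, n, n))
        for k, lf in enumerate(freqs.loci):
            f = lf.freqs
            jx[k] = np.sum(f**2, axis=1)
            jxy[k] = f @ f.T

        def build(idx):
            mjx = jx[idx].mean(axis=0)
            mjxy = jxy[idx].mean(axis=0)
            with np.errstate(divide="ignore"):
                m = -np.log(mjxy / np.sqrt(np.outer(mjx, mjx)))
            np.fill_diagonal(m, 0.0)
            return PairwiseMatrix(list(pops), m, "Ds")

        return build
    if statistic == "fst":
        # per-locus numerator and denominator sums for every pair
        num = np.zeros((L, n, n))
        den = np.zeros((L, n, n))
        for i in range(n):
            for j in range(i + 1, n):
                comp = wc_components(freqs, [pops[i], pops[j]])
                for k, lname in enumerate([lf.locus for lf in freqs.loci]):
                    if lname in comp.a:
                        num[k, i, j] = comp.a[lname].sum()
                        den[k, i, j] = (
                            comp.a[lname].sum() + comp.b[lname].sum() + comp.c[lname].sum()
                        )

        def build(idx):
            nn = num[idx].sum(axis=0)
            dd = den[idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.where(dd != 0, nn / np.maximum(dd, 1e-300), 0.0)
            m = m + m.T
            np.fill_diagonal(m, 0.0)
            return PairwiseMatrix(list(pops), m, "FST")

        return build
    raise ValueError(f"unknown bootstrap statistic {statistic!r}")


def bootstrap_distance(
    freqs: AlleleFrequencyTable,
    statistic: str,
    B: int,
    seed: int | None = None,
    sizes: AlleleSizeMap | None = None,
) -> BootstrapReplicates:
    """Bootstrap a pairwise distance over loci (B replicates, seeded)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    L = len(freqs.loci)
    if L < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(B, L))
    build = _per_locus_ingredients(freqs, statistic, sizes)
    matrices = [build(idx[b]) for b in range(B)]
    return BootstrapReplicates(statistic, B, seed, idx, matrices)
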