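"""Weir–Cockerham F_ST, the among/within variance partition, and gene flow.

θ is the ratio estimator Σa / Σ(a+b+c) over loci and alleles, where a, b, c
are the among-population, among-individual-within-population and
within-individual variance components of the Weir & Cockerham (1984)
analysis of variance for allele frequencies.  Gene flow Nm follows Wright's
island model, Nm = (1 − F_ST) / (4 F_ST).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AlleleFrequencyTable, GenotypeDataset, allele_frequencies
from .matrix import PairwiseMatrix

__all__ = [
    "VarianceComponents",
    "wc_components",
    "fst_global",
    "fst_pairwise",
    "fst_leave_group_out",
    "nm_from_fst",
    "fst_permutation_test",
]

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Per-(locus, allele) variance components a, b, c.

    ``a[locus]`` etc. are arrays over the alleles of that locus;
    c = h̄/2 is always nonnegative.
    """

    populations: list[str]
    loci: list[str]
    a: dict[str, np.ndarray] = field(default_factory=dict)
    b: dict[str, np.ndarray] = field(default_factory=dict)
    c: dict[str, np.ndarray] = field(default_factory=dict)

    def sums(self) -> tuple[float, float]:
        """(Σa, Σ(a+b+c)) over all loci and alleles."""
        num = sum(float(self.a[l].sum()) for l in self.loci)
        den = sum(
            float(self.a[l].sum() + self.b[l].sum() + self.c[l].sum()) for l in self.loci
        )
        return num, den


def wc_components(
    freqs: AlleleFrequencyTable, populations: list[str] | None = None
) -> VarianceComponents:
    """Weir–Cockerham variance components for r ≥ 2 populations.

    For each locus and allele, with n_i typed individuals, p_i the allele
    frequency and h_i the observed-heterozygote frequency in population i:

        n̄  = Σn_i / r
        n_c = (r n̄ − Σn_i²/(r n̄)) / (r − 1)
        p̄  = Σ n_i p_i / (r n̄)
        s² = Σ n_i (p_i − p̄)² / ((r − 1) n̄)
        h̄  = Σ n_i h_i / (r n̄)
        a  = (n̄/n_c) [s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4) / (n̄−1)]
        b  = (n̄/(n̄−1)) [p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
        c  = h̄/2

    Loci at which any selected population has no data are dropped with a
    logged warning.
    """
    if populations is not None:
        freqs = freqs.subset_populations(populations)
    r = len(freqs.populations)
    if r < 2:
        raise ValueError("need at least 2 populations")
    out = VarianceComponents(list(freqs.populations), [])
    for lf in freqs.loci:
        if lf.empty.any():
            log.warning(
                "locus %s dropped: no data for population(s) %s",
                lf.locus,
                [p for p, e in zip(freqs.populations, lf.empty) if e],
            )
            continue
        n = lf.n_ind.astype(float)          # (P,)
        p = lf.freqs                         # (P, A)
        h = lf.het_freqs                     # (P, A)
        nbar = n.mean()
        if nbar <= 1:
            log.warning("locus %s dropped: mean sample size <= 1", lf.locus)
            continue
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)          # (A,)
        s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        out.loci.append(lf.locus)
        out.a[lf.locus] = a
        out.b[lf.locus] = b
        out.c[lf.locus] = c
    if not out.loci:
        raise ValueError("no locus shared with data across all selected populations")
    return out


def fst_global(components: VarianceComponents) -> tuple[float, float, float]:
    """Multi-locus θ and the percent variation among / within populations.

    Returns (θ, percent-among, percent-within) with percent-among = 100 θ.
    """
    num, den = components.sums()
    if den == 0:
        raise ValueError("all loci monomorphic: θ undefined")
    theta = num / den
    return theta, 100.0 * theta, 100.0 * (1.0 - theta)


def fst_pairwise(freqs: AlleleFrequencyTable) -> PairwiseMatrix:
    """Pairwise θ for every population pair (r = 2 ratio estimator).

    Negative estimates are reported as computed, not truncated.
    """
    pops = freqs.populations
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = wc_components(freqs, [pops[i], pops[j]])
            theta, _, _ = fst_global(comp)
            m[i, j] = m[j, i] = theta
    return PairwiseMatrix(list(pops), m, "FST")


def fst_leave_group_out(
    freqs: AlleleFrequencyTable, drop: list[str]
) -> tuple[float, float, float]:
    """Global θ recomputed after removing the named populations."""
    keep = [p for p in freqs.populations if p not in set(drop)]
    result = fst_global(wc_components(freqs, keep))
    log.info("global θ without %s: %.4f (%.1f%% among)", drop, result[0], result[1])
    return result


def nm_from_fst(fst: PairwiseMatrix | float):
    """Wright's island-model gene flow, Nm = (1 − F_ST)/(4 F_ST).

    Non-positive F_ST (no detectable differentiation) maps to the +inf
    sentinel with a warning; the diagonal of a matrix input is also +inf.
    """

    def transform(v: np.ndarray) -> np.ndarray:
        nonpos = v <= 0
        if nonpos.any():
            log.warning("%d non-positive F_ST entries -> Nm = +inf", int(nonpos.sum()))
        with np.errstate(divide="ignore"):
            out = np.where(nonpos, np.inf, (1.0 - v) / (4.0 * np.maximum(v, 1e-300)))
        return out

    if isinstance(fst, PairwiseMatrix):
        out = fst.apply(transform, statistic="Nm")
        np.fill_diagonal(out.values, np.inf)
        return out
    return float(transform(np.array([float(fst)]))[0])


def fst_permutation_test(
    ds: GenotypeDataset,
    populations: list[str] | None = None,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation significance of θ (individuals shuffled among populations).

    Returns (θ observed, p-value) where p is the fraction of permuted
    datasets with θ at least as large, with the +1 small-sample correction.
    """
    if populations is not None:
        ds = ds.subset(populations=populations)
    theta_obs = fst_global(wc_components(allele_frequencies(ds)))[0]
    rng = np.random.default_rng(seed)
    labels = np.asarray(ds.populations, dtype=object)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        ds_perm = GenotypeDataset(
            ds.individuals, list(perm), ds.loci, ds.calls, validate_sizes=False
        )
        t = fst_global(wc_components(allele_frequencies(ds_perm)))[0]
        if t >= theta_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return theta_obs, p
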