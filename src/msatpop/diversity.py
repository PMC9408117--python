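"""Per-locus marker diversity summaries.

Computes, for each microsatellite locus, the total number of alleles (TNA),
rarefied allelic richness (AR), polymorphism information content (PIC), and
observed/expected heterozygosity, plus the column mean and sample standard
deviation — the familiar marker-panel characterization table.

Statistics are computed on the pooled sample across populations (one row
per locus); per-population variants are available via
:func:`per_population_table`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import AlleleFrequencyTable, LocusFrequencies

__all__ = [
    "LocusDiversity",
    "pic",
    "rarefied_richness",
    "expected_het_unbiased",
    "heterozygosities",
    "locus_summary",
    "per_population_table",
]

log = logging.getLogger(__name__)


@dataclass
class LocusDiversity:
    locus: str
    TNA: int
    AR: float
    PIC: float
    Ho: float
    He: float


def pic(p: np.ndarray) -> float:
    """Polymorphism information content of an allele-frequency vector.

    PIC = 1 − Σ_a p_a² − Σ_{a<b} 2 p_a² p_b² (Botstein's measure).  The
    pairwise double sum collapses to (Σp²)² − Σp⁴.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2**2 - s4)


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    Hypergeometric rarefaction: AR(g) = Σ_a [1 − C(N−N_a, g) / C(N, g)]
    with N the total gene copies and N_a the copies of allele a.  Computed
    in log space for numerical stability at large N.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds N={N} gene copies")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = N - counts  # copies not of allele a
    with np.errstate(divide="ignore"):
        term = np.where(
            rest >= g, np.exp(log_choose(rest, g) - log_choose(N, g)), 0.0
        )
    return float(np.sum(1.0 - term))


def expected_het_unbiased(counts: np.ndarray) -> float:
    """Nei's unbiased expected heterozygosity from gene-copy counts.

    He = n/(n−1) · (1 − Σp²) with n the gene copies (2 × individuals).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("He undefined for fewer than 2 gene copies")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _pooled_ho(lf: LocusFrequencies) -> float:
    # each heterozygous individual is counted once for each of its 2 alleles
    n_het = lf.het_counts.sum() / 2.0
    n_tot = lf.n_ind.sum()
    return float(n_het / n_tot) if n_tot else float("nan")


def heterozygosities(freqs: AlleleFrequencyTable) -> pd.DataFrame:
    """Pooled-sample observed and unbiased expected heterozygosity per locus."""
    rows = []
    for lf in freqs.loci:
        pooled = lf.pooled_counts()
        rows.append(
            {
                "locus": lf.locus,
                "Ho": _pooled_ho(lf),
                "He": expected_het_unbiased(pooled) if pooled.sum() >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def _auto_g(lf: LocusFrequencies) -> int:
    """Default rarefaction size: smallest per-population gene-copy count.

    Guarantees every sampled population could supply g copies, making AR
    comparable across loci with unequal sample sizes.
    """
    nc = lf.n_copies[lf.n_copies > 0]
    return int(nc.min()) if len(nc) else 0


def locus_summary(
    freqs: AlleleFrequencyTable, rarefaction_g: int | str = "auto"
) -> pd.DataFrame:
    """Marker-panel summary table: one row per locus + Average and SD rows.

    TNA, PIC, He are computed on the sample pooled over populations; AR by
    hypergeometric rarefaction to ``rarefaction_g`` gene copies (``"auto"``:
    the smallest per-population gene-copy count at each locus, logged).
    The Average/SD rows use the arithmetic mean and the n−1 sample SD.
    """
    if not freqs.loci:
        raise ValueError("no loci with data")
    rows = []
    for lf in freqs.loci:
        pooled = lf.pooled_counts()
        N = int(pooled.sum())
        if N == 0:
            log.warning("locus %s has no data; skipped", lf.locus)
            continue
        g = _auto_g(lf) if rarefaction_g == "auto" else int(rarefaction_g)
        log.debug("locus %s: rarefaction g=%d (N=%d)", lf.locus, g, N)
        p = pooled / N
        rows.append(
            LocusDiversity(
                locus=lf.locus,
                TNA=int((pooled > 0).sum()),
                AR=rarefied_richness(pooled, g),
                PIC=pic(p),
                Ho=_pooled_ho(lf),
                He=expected_het_unbiased(pooled) if N >= 2 else float("nan"),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("locus")
    stats = df[["TNA", "AR", "PIC", "Ho", "He"]]
    df.loc["Average"] = stats.mean()
    df.loc["SD"] = stats.std(ddof=1)
    return df


def per_population_table(freqs: AlleleFrequencyTable) -> pd.DataFrame:
    """Per-(population, locus) allele counts and heterozygosities."""
    rows = []
    for lf in freqs.loci:
        for pi, pop in enumerate(freqs.populations):
            n = int(lf.n_ind[pi])
            counts = lf.counts[pi]
            rows.append(
                {
                    "population": pop,
                    "locus": lf.locus,
                    "n": n,
                    "n_alleles": int((counts > 0).sum()),
                    "Ho": float(lf.het_counts[pi].sum() / 2 / n) if n else float("nan"),
                    "He": expected_het_unbiased(counts) if n >= 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
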