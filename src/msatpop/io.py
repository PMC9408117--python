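"""Genotype data model and readers/writers for GENEPOP, STRUCTURE and CSV.

Alleles are integer codes — microsatellite fragment sizes in base pairs for
lab data, or repeat counts for simulated data.  A genotype is an unordered
pair of allele codes; missing genotypes are wholly missing (both copies),
encoded internally by the :data:`MISSING` sentinel and normalized on read
from each format's native convention (``000`` in GENEPOP, ``-9`` in
STRUCTURE, empty cells in CSV).
"""
from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "LocusMeta",
    "GenotypeDataset",
    "LocusFrequencies",
    "AlleleFrequencyTable",
    "GenotypeParseError",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
    "qc_missingness",
    "filter_missing",
]

MISSING: int = -1


class GenotypeParseError(ValueError):
    """Malformed record in a genotype file (carries line number and field)."""


class GenotypeValidationError(ValueError):
    """Structurally parseable input violating a dataset invariant."""


@dataclass(frozen=True)
class LocusMeta:
    """Descriptive metadata for one microsatellite locus.

    ``motif_length`` is the tandem-repeat unit in bp (2 for dinucleotides);
    ``size_range`` bounds legal fragment sizes when alleles are coded in bp.
    """

    name: str
    motif_length: int = 2
    size_range: tuple[int, int] | None = None
    chromosome: str | None = None

    def __post_init__(self):
        if self.motif_length < 1:
            raise ValueError(f"{self.name}: motif_length must be >= 1")
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValueError(f"{self.name}: size_range min > max")


class GenotypeDataset:
    """Diploid multi-allelic genotypes for individuals grouped in populations.

    ``calls`` has shape (n_individuals, n_loci, 2); each pair is stored
    sorted ascending, and a missing genotype is ``(MISSING, MISSING)`` —
    half-missing genotypes are rejected at construction.
    """

    def __init__(
        self,
        individuals: list[str],
        populations: list[str],
        loci: list[LocusMeta],
        calls: np.ndarray,
        validate_sizes: bool = True,
    ):
        if len(individuals) != len(set(individuals)):
            dup = sorted({x for x in individuals if individuals.count(x) > 1})
            raise GenotypeValidationError(f"duplicate individual id(s): {dup}")
        if len(populations) != len(individuals):
            raise GenotypeValidationError("one population label per individual required")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(loci), 2):
            raise GenotypeValidationError(
                f"calls shape {calls.shape} != ({len(individuals)}, {len(loci)}, 2)"
            )
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise GenotypeValidationError(
                f"half-missing genotype for individual {individuals[i]!r} "
                f"at locus {loci[l].name!r}"
            )
        calls = np.sort(calls, axis=2)
        if validate_sizes:
            for l, lm in enumerate(loci):
                if lm.size_range is None:
                    continue
                col = calls[:, l, :]
                ok = (col == MISSING) | ((col >= lm.size_range[0]) & (col <= lm.size_range[1]))
                if not ok.all():
                    i = int(np.argwhere(~ok)[0][0])
                    raise GenotypeValidationError(
                        f"allele {col[~ok][0]} outside declared size_range "
                        f"{lm.size_range} at locus {lm.name!r} "
                        f"(individual {individuals[i]!r})"
                    )
        self.individuals = list(individuals)
        self.populations = list(populations)
        self.loci = list(loci)
        self.calls = calls

    # -- basic views -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [lm.name for lm in self.loci]

    @property
    def pop_names(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.populations, dtype=object) == pop)

    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean: genotype missing."""
        return self.calls[:, :, 0] == MISSING

    def subset(
        self,
        individuals: list[str] | None = None,
        loci: list[str] | None = None,
        populations: list[str] | None = None,
    ) -> "GenotypeDataset":
        ii = np.arange(self.n_individuals)
        if populations is not None:
            keep = set(populations)
            ii = np.array([i for i in ii if self.populations[i] in keep], dtype=int)
        if individuals is not None:
            keep = set(individuals)
            ii = np.array([i for i in ii if self.individuals[i] in keep], dtype=int)
        ll = np.arange(self.n_loci)
        if loci is not None:
            keepl = set(loci)
            ll = np.array([l for l in ll if self.loci[l].name in keepl], dtype=int)
        return GenotypeDataset(
            [self.individuals[i] for i in ii],
            [self.populations[i] for i in ii],
            [self.loci[l] for l in ll],
            self.calls[np.ix_(ii, ll)],
            validate_sizes=False,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeDataset)
            and self.individuals == other.individuals
            and self.populations == other.populations
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class LocusFrequencies:
    """Per-population allele counts at one locus over a shared allele set.

    ``alleles`` is sorted ascending (canonical order); ``counts[i, a]`` is
    the gene-copy count of allele ``a`` in population ``i``, ``het_counts``
    the number of heterozygous individuals carrying it, and ``n_ind`` the
    non-missing individuals per population.
    """

    locus: str
    alleles: np.ndarray          # (A,) sorted allele codes
    counts: np.ndarray           # (P, A)
    het_counts: np.ndarray       # (P, A)
    n_ind: np.ndarray            # (P,)

    @property
    def n_copies(self) -> np.ndarray:
        return 2 * self.n_ind

    @property
    def empty(self) -> np.ndarray:
        """Populations with zero non-missing calls at this locus."""
        return self.n_ind == 0

    @property
    def freqs(self) -> np.ndarray:
        """(P, A) frequencies; rows of empty populations are all zero."""
        denom = np.where(self.n_ind > 0, 2 * self.n_ind, 1)
        return self.counts / denom[:, None]

    @property
    def het_freqs(self) -> np.ndarray:
        """(P, A) observed heterozygote frequency per allele."""
        denom = np.where(self.n_ind > 0, self.n_ind, 1)
        return self.het_counts / denom[:, None]

    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class AlleleFrequencyTable:
    """Allele frequencies per (population, locus) — the substrate of every
    downstream statistic."""

    populations: list[str]
    loci: list[LocusFrequencies]

    @property
    def locus_names(self) -> list[str]:
        return [lf.locus for lf in self.loci]

    def locus(self, name: str) -> LocusFrequencies:
        return self.loci[self.locus_names.index(name)]

    def subset_populations(self, populations: list[str]) -> "AlleleFrequencyTable":
        idx = [self.populations.index(p) for p in populations]
        return AlleleFrequencyTable(
            list(populations),
            [
                LocusFrequencies(
                    lf.locus, lf.alleles, lf.counts[idx], lf.het_counts[idx], lf.n_ind[idx]
                )
                for lf in self.loci
            ],
        )


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Tabulate per-population allele frequencies over non-missing calls.

    Frequencies are computed over 2 × (observed individuals); missing
    genotypes are excluded, never imputed.  The allele set at each locus is
    shared across populations (alleles absent from a population get p = 0)
    and sorted ascending by code.
    """
    pops = ds.pop_names
    pop_idx = {p: ds.pop_indices(p) for p in pops}
    loci_out = []
    for l, lm in enumerate(ds.loci):
        col = ds.calls[:, l, :]
        present = col[:, 0] != MISSING
        alleles = np.unique(col[present])
        a_index = {a: i for i, a in enumerate(alleles)}
        P, A = len(pops), len(alleles)
        counts = np.zeros((P, A), dtype=np.int64)
        het = np.zeros((P, A), dtype=np.int64)
        n_ind = np.zeros(P, dtype=np.int64)
        for pi, p in enumerate(pops):
            rows = col[pop_idx[p]]
            rows = rows[rows[:, 0] != MISSING]
            n_ind[pi] = len(rows)
            if not len(rows):
                continue
            flat = rows.ravel()
            for a, c in zip(*np.unique(flat, return_counts=True)):
                counts[pi, a_index[a]] = c
            hz = rows[rows[:, 0] != rows[:, 1]]
            for a, c in zip(*np.unique(hz.ravel(), return_counts=True)):
                het[pi, a_index[a]] = c
        loci_out.append(LocusFrequencies(lm.name, alleles, counts, het, n_ind))
    return AlleleFrequencyTable(pops, loci_out)


# ---------------------------------------------------------------------------
# missingness QC
# ---------------------------------------------------------------------------


def qc_missingness(ds: GenotypeDataset) -> dict[str, pd.Series]:
    """Per-locus and per-individual missing-genotype rates in [0, 1]."""
    m = ds.missing_mask()
    return {
        "locus": pd.Series(m.mean(axis=0), index=ds.locus_names, name="missing_rate"),
        "individual": pd.Series(m.mean(axis=1), index=ds.individuals, name="missing_rate"),
    }


def filter_missing(
    ds: GenotypeDataset,
    max_locus_rate: float | None = None,
    max_individual_rate: float | None = None,
) -> tuple[GenotypeDataset, dict]:
    """Drop loci/individuals whose missing rate exceeds a threshold.

    Returns the filtered dataset and a report of what was removed.
    """
    rates = qc_missingness(ds)
    drop_loci: list[str] = []
    drop_ind: list[str] = []
    if max_locus_rate is not None:
        drop_loci = list(rates["locus"][rates["locus"] > max_locus_rate].index)
    if max_individual_rate is not None:
        drop_ind = list(rates["individual"][rates["individual"] > max_individual_rate].index)
    keep_loci = [n for n in ds.locus_names if n not in set(drop_loci)]
    keep_ind = [n for n in ds.individuals if n not in set(drop_ind)]
    out = ds.subset(individuals=keep_ind, loci=keep_loci)
    return out, {"dropped_loci": drop_loci, "dropped_individuals": drop_ind}


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_FORMATS = ("genepop", "structure", "csv")


def read_genotypes(
    path, format: str, locus_meta: list[LocusMeta] | None = None
) -> GenotypeDataset:
    """Read a genotype file in GENEPOP, STRUCTURE two-row, or long-CSV format.

    When ``locus_meta`` is given it overrides the bare locus names found in
    the file (and enables fragment-size validation).
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {_FORMATS}")
    text = Path(path).read_text()
    reader = {"genepop": _read_genepop, "structure": _read_structure, "csv": _read_csv}[format]
    inds, pops, locus_names, calls = reader(text, str(path))
    loci = _resolve_meta(locus_names, locus_meta)
    return GenotypeDataset(inds, pops, loci, calls)


def write_genotypes(ds: GenotypeDataset, path, format: str) -> None:
    """Write a dataset; the output re-reads to an equal dataset."""
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {_FORMATS}")
    writer = {"genepop": _write_genepop, "structure": _write_structure, "csv": _write_csv}[format]
    Path(path).write_text(writer(ds))


def _resolve_meta(
    names: list[str], locus_meta: list[LocusMeta] | None
) -> list[LocusMeta]:
    if locus_meta is None:
        return [LocusMeta(n) for n in names]
    by_name = {lm.name: lm for lm in locus_meta}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise GenotypeValidationError(f"no metadata for loci: {missing}")
    return [by_name[n] for n in names]


# -- GENEPOP ---------------------------------------------------------------


def _is_pop_line(line: str) -> bool:
    toks = line.split()
    return bool(toks) and toks[0].lower() == "pop"


def _read_genepop(text: str, path: str):
    lines = text.splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    # locus names: one per line or comma-separated, until the first "Pop"
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _is_pop_line(lines[i]):
        chunk = [x.strip() for x in lines[i].split(",") if x.strip()]
        locus_names.extend(chunk)
        i += 1
    inds: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_counter = 0
    pop_label = ""
    while i < len(lines):
        if _is_pop_line(lines[i]):
            pop_counter += 1
            toks = lines[i].split()
            # our writer puts the population label after "Pop"; bare "Pop"
            # separators (the strict dialect) get sequential names
            pop_label = toks[1] if len(toks) > 1 else f"Pop{pop_counter}"
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise GenotypeParseError(f"{path}:{i + 1}: expected 'id , genotypes' record")
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        fields = geno_part.split()
        if len(fields) != len(locus_names):
            raise GenotypeParseError(
                f"{path}:{i + 1}: {len(fields)} genotype fields for "
                f"{len(locus_names)} loci (individual {ind_id!r})"
            )
        row: list[int] = []
        for lname, f in zip(locus_names, fields):
            if len(f) not in (4, 6) or not f.isdigit():
                raise GenotypeParseError(
                    f"{path}:{i + 1}: bad genotype field {f!r} at locus {lname!r} "
                    "(expected 4 or 6 digits)"
                )
            w = len(f) // 2
            a1, a2 = int(f[:w]), int(f[w:])
            row.extend([MISSING if a1 == 0 else a1, MISSING if a2 == 0 else a2])
        inds.append(ind_id)
        pops.append(pop_label)
        rows.append(row)
        i += 1
    calls = (
        np.array(rows, dtype=np.int64).reshape(len(inds), len(locus_names), 2)
        if inds
        else np.empty((0, len(locus_names), 2), dtype=np.int64)
    )
    return inds, pops, locus_names, calls


def _write_genepop(ds: GenotypeDataset) -> str:
    width = 3 if not ds.n_individuals or ds.calls.max() < 1000 else 6
    out = ["msatpop genotypes"]
    out.extend(ds.locus_names)
    last_pop = None
    for i, (ind, pop) in enumerate(zip(ds.individuals, ds.populations)):
        if pop != last_pop:
            out.append(f"Pop {pop}")
            last_pop = pop
        fields = []
        for l in range(ds.n_loci):
            a1, a2 = ds.calls[i, l]
            fields.append(
                f"{max(a1, 0):0{width}d}{max(a2, 0):0{width}d}"
            )
        out.append(f"{ind} , " + " ".join(fields))
    return "\n".join(out) + "\n"


# -- STRUCTURE two-row ------------------------------------------------------


def _read_structure(text: str, path: str):
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    # header row holds the L locus names; data rows hold L + 2 columns
    locus_names = lines[0].split()
    body = lines[1:]
    if body and len(body[0].split()) != len(locus_names) + 2:
        raise GenotypeParseError(
            f"{path}: data rows must have {len(locus_names) + 2} columns "
            "(id, population, one per locus)"
        )
    if len(body) % 2:
        raise GenotypeParseError(f"{path}: odd number of data rows (two rows per individual)")
    inds, pops, rows = [], [], []
    for r in range(0, len(body), 2):
        t1, t2 = body[r].split(), body[r + 1].split()
        if len(t1) != len(locus_names) + 2 or len(t2) != len(locus_names) + 2:
            raise GenotypeParseError(f"{path}: row {r + 2}: wrong column count")
        if t1[0] != t2[0] or t1[1] != t2[1]:
            raise GenotypeParseError(
                f"{path}: rows {r + 2}-{r + 3}: id/population mismatch "
                f"({t1[0]}/{t1[1]} vs {t2[0]}/{t2[1]})"
            )
        try:
            a1 = [int(x) for x in t1[2:]]
            a2 = [int(x) for x in t2[2:]]
        except ValueError as e:
            raise GenotypeParseError(f"{path}: rows {r + 2}-{r + 3}: {e}") from None
        inds.append(t1[0])
        pops.append(t1[1])
        rows.append(
            [
                v
                for pair in zip(a1, a2)
                for v in (
                    MISSING if pair[0] == -9 else pair[0],
                    MISSING if pair[1] == -9 else pair[1],
                )
            ]
        )
    calls = (
        np.array(rows, dtype=np.int64).reshape(len(inds), len(locus_names), 2)
        if inds
        else np.empty((0, len(locus_names), 2), dtype=np.int64)
    )
    return inds, pops, locus_names, calls


def _write_structure(ds: GenotypeDataset) -> str:
    out = [" ".join(ds.locus_names)]
    for i, (ind, pop) in enumerate(zip(ds.individuals, ds.populations)):
        for c in (0, 1):
            alleles = [
                str(a if a != MISSING else -9) for a in ds.calls[i, :, c]
            ]
            out.append(" ".join([ind, pop] + alleles))
    return "\n".join(out) + "\n"


# -- long CSV ---------------------------------------------------------------

_CSV_HEADER = ["individual", "population", "locus", "allele1", "allele2"]


def _read_csv(text: str, path: str):
    reader = _csv.reader(text.splitlines())
    rows = list(reader)
    if not rows or [c.strip() for c in rows[0]] != _CSV_HEADER:
        raise GenotypeParseError(f"{path}: expected header {','.join(_CSV_HEADER)}")
    inds: list[str] = []
    pops_of: dict[str, str] = {}
    locus_names: list[str] = []
    cells: dict[tuple[str, str], tuple[int, int]] = {}
    for ln, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        if len(row) != 5:
            raise GenotypeParseError(f"{path}:{ln}: expected 5 columns, got {len(row)}")
        ind, pop, locus, s1, s2 = (c.strip() for c in row)
        if ind not in pops_of:
            inds.append(ind)
            pops_of[ind] = pop
        elif pops_of[ind] != pop:
            raise GenotypeParseError(
                f"{path}:{ln}: individual {ind!r} listed under two populations"
            )
        if locus not in locus_names:
            locus_names.append(locus)
        if (s1 == "") != (s2 == ""):
            raise GenotypeValidationError(
                f"{path}:{ln}: half-missing genotype for {ind!r} at {locus!r}"
            )
        try:
            pair = (MISSING, MISSING) if s1 == "" else (int(s1), int(s2))
        except ValueError:
            raise GenotypeParseError(f"{path}:{ln}: non-integer allele in {row}") from None
        if (ind, locus) in cells:
            raise GenotypeParseError(f"{path}:{ln}: duplicate record for ({ind}, {locus})")
        cells[(ind, locus)] = pair
    calls = np.full((len(inds), len(locus_names), 2), MISSING, dtype=np.int64)
    for (ind, locus), (a1, a2) in cells.items():
        calls[inds.index(ind), locus_names.index(locus)] = (a1, a2)
    return inds, [pops_of[i] for i in inds], locus_names, calls


def _write_csv(ds: GenotypeDataset) -> str:
    out = [",".join(_CSV_HEADER)]
    for i, (ind, pop) in enumerate(zip(ds.individuals, ds.populations)):
        for l, name in enumerate(ds.locus_names):
            a1, a2 = ds.calls[i, l]
            s1, s2 = ("", "") if a1 == MISSING else (str(a1), str(a2))
            out.append(",".join([ind, pop, name, s1, s2]))
    return "\n".join(out) + "\n"
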