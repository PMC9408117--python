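"""Packaged summary tables from the source study of 11 western
Mediterranean sheep breeds (975 animals, 17 microsatellites).

The study's raw genotypes were not deposited; its published summary
tables are shipped here so the marker-panel statistics and the
divergence-time calibration can be re-derived offline:

* the marker panel (locus, fragment-size window, chromosome, TNA, AR, PIC);
* pairwise F_ST, Nei's Ds and (δµ)² between the 11 breeds;
* the published divergence times in years.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .matrix import PairwiseMatrix

__all__ = [
    "load_study_loci",
    "load_study_fst",
    "load_study_ds",
    "load_study_dmu2",
    "load_study_years",
    "BREED_GROUPS",
]

#: breed → group (Maghrebian vs South European), for labeling and plots
BREED_GROUPS = {
    "BAR": "Maghrebian", "QFO": "Maghrebian", "CRO": "Maghrebian",
    "DM": "Maghrebian", "SS": "Maghrebian", "NTH": "Maghrebian",
    "ALP": "South European", "BRO": "South European",
    "FOZ": "South European", "LAM": "South European", "APP": "South European",
}


def _path(name: str):
    return resources.files("msatpop.data").joinpath(name)


def load_study_loci() -> pd.DataFrame:
    """Marker panel table: one row per locus with TNA, AR and PIC."""
    with resources.as_file(_path("study_loci.csv")) as p:
        return pd.read_csv(p)


def _load_matrix(name: str, statistic: str) -> PairwiseMatrix:
    with resources.as_file(_path(name)) as p:
        return PairwiseMatrix.from_csv(p, statistic)


def load_study_fst() -> PairwiseMatrix:
    return _load_matrix("study_fst.csv", "FST")


def load_study_ds() -> PairwiseMatrix:
    return _load_matrix("study_ds.csv", "Ds")


def load_study_dmu2() -> PairwiseMatrix:
    return _load_matrix("study_dmu2.csv", "dmu2")


def load_study_years() -> PairwiseMatrix:
    return _load_matrix("study_divergence_years.csv", "years")
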