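"""Bundled reference tables from a published-scale cattle CNV cohort.

These small tables describe the most widely shared duplications and
deletions — cohort-wide and per breed — observed in a 146-animal, 13-breed
*Bos taurus* whole-genome study, together with the post-QC sizes of the five
most numerous breeds.  They serve as worked examples for the annotation
classifier and the sharing-percentage arithmetic.
"""
from __future__ import annotations

from importlib import resources
from typing import Dict

import pandas as pd

#: Animals per breed after the 7-fold coverage exclusion: one Fleckvieh and
#: seven Norwegian Red animals of the original 31 and 26 were removed.
KEPT_BREED_SIZES: Dict[str, int] = {
    "BSW": 48,  # Brown Swiss
    "FLV": 30,  # Fleckvieh
    "RED": 19,  # Norwegian Red
    "GUE": 20,  # Guernsey
    "SIM": 16,  # Simmental
}

BREED_NAMES: Dict[str, str] = {
    "BSW": "Brown Swiss",
    "FLV": "Fleckvieh",
    "RED": "Norwegian Red",
    "GUE": "Guernsey",
    "SIM": "Simmental",
}

#: Reference genome length used in the cohort's coverage formula (UMD3.1).
REFERENCE_GENOME_BP = 2_697_560_000


def _load(name: str) -> pd.DataFrame:
    with resources.files("cnvcohort.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_common_cnvs(cnv_type: str) -> pd.DataFrame:
    """The 20 most widely shared cohort CNVs of a type, with location labels."""
    if cnv_type == "DUP":
        return _load("common_duplications.tsv")
    if cnv_type == "DEL":
        return _load("common_deletions.tsv")
    raise ValueError(f"unknown CNV type {cnv_type!r}")


def load_breed_specific_cnvs(cnv_type: str) -> pd.DataFrame:
    """Most widely shared breed-specific CNVs of a type, per breed."""
    if cnv_type == "DUP":
        return _load("breed_specific_duplications.tsv")
    if cnv_type == "DEL":
        return _load("breed_specific_deletions.tsv")
    raise ValueError(f"unknown CNV type {cnv_type!r}")
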