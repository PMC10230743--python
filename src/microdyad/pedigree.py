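"""Dyadic kinship covariates from a pedigree.

Relatedness follows the four-value coding used for dyadic microbiota models:
parent-offspring and full siblings 0.5, half siblings (exactly one shared
recorded parent) 0.25, everything else 0. Only first-degree and half-sibling
links are coded; deeper pedigree arithmetic (grandparents, cousins) maps to 0.
Missing parents are distinct unknowns: two individuals with unrecorded
mothers are not half siblings.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class PedigreeTable:
    """individual id -> (mother_id, father_id, sex); NA where unknown."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("mother_id", "father_id"):
            if col not in self.data.columns:
                raise ValueError(f"pedigree missing column {col!r}")
        for ind in self.data.index:
            mom = self.data.at[ind, "mother_id"]
            if pd.notna(mom) and mom == ind:
                raise ValueError(f"{ind!r} is its own mother")
            dad = self.data.at[ind, "father_id"]
            if pd.notna(dad) and dad == ind:
                raise ValueError(f"{ind!r} is its own father")
        if "sex" in self.data.columns:
            moms = self.data["mother_id"].dropna().unique()
            known = self.data["sex"].reindex(moms).dropna()
            males = known[known == "M"]
            if len(males):
                raise ValueError(f"recorded mothers with male sex: {list(males.index)}")

    def _check(self, *inds: str) -> None:
        for ind in inds:
            if ind not in self.data.index:
                raise KeyError(f"individual {ind!r} not in pedigree")

    def parents(self, ind: str):
        self._check(ind)
        mom = self.data.at[ind, "mother_id"]
        dad = self.data.at[ind, "father_id"]
        return (None if pd.isna(mom) else mom, None if pd.isna(dad) else dad)


def mother_offspring(ped: PedigreeTable, a: str, b: str) -> int:
    """1 iff one member is the recorded mother of the other (father-offspring -> 0)."""
    ped._check(a, b)
    mom_a, _ = ped.parents(a)
    mom_b, _ = ped.parents(b)
    return int(mom_a == b or mom_b == a)


def relatedness(ped: PedigreeTable, a: str, b: str) -> float:
    """Pedigree relatedness in {0, 0.25, 0.5} (see module docstring)."""
    ped._check(a, b)
    if a == b:
        raise ValueError("relatedness is defined for distinct individuals")
    mom_a, dad_a = ped.parents(a)
    mom_b, dad_b = ped.parents(b)
    # parent-offspring (either parent)
    if b in (mom_a, dad_a) or a in (mom_b, dad_b):
        return 0.5
    shared = 0
    if mom_a is not None and mom_a == mom_b:
        shared += 1
    if dad_a is not None and dad_a == dad_b:
        shared += 1
    if shared == 2:
        return 0.5  # full siblings
    if shared == 1:
        return 0.25  # half siblings
    return 0.0


def read_pedigree_csv(path) -> PedigreeTable:
    """Pedigree CSV: individual_id, mother_id, father_id, sex; blank = unknown."""
    df = pd.read_csv(path, index_col="individual_id", dtype=str)
    return PedigreeTable(df)


def write_pedigree_csv(ped: PedigreeTable, path) -> None:
    ped.data.to_csv(path, index_label="individual_id")
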