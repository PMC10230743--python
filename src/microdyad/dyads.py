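"""Assemble the dyadic (sample-pair) dataset and apply exclusion filters.

Each row is one unordered between-individual pair of samples, with the
response (microbiota similarity) and all dyadic covariates:

- mo_status: 1 iff the two individuals are a mother-offspring pair
- relatedness: pedigree coefficient in {0, 0.25, 0.5}
- sri: adjusted Simple Ratio Index of the two individuals
- age_sim / sex_sim: 1 if same age class / sex, else 0
- spatial_dist: distance between the individuals' logger centroids (m)
- interval_days: absolute difference between sampling dates

Two exclusion filters are applied, with full bookkeeping: (i) pairs where
both samples are immature, and (ii) mother-offspring pairs where the
mother's sample is immature. After (ii), a mother-offspring pair can differ
in age class only when the offspring is the immature member, which is what
lets the mother-offspring x age-class-similarity interaction be read as an
offspring-age effect. The two removal sets can overlap; the report states
the intersection explicitly rather than assuming disjointness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable, mother_offspring, relatedness
from .socialnet import SriMatrix, spatial_distance
from .taxa import SimilarityMatrix

META_COLUMNS = ("sample_id", "individual_id", "date", "age_class", "sex")
AGE_CLASSES = ("immature", "adult")

#: continuous covariates centred/scaled by default
CONTINUOUS_COVARIATES = ("sri", "relatedness", "spatial_dist", "interval_days")


def read_metadata_csv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
    bad = set(meta["age_class"]) - set(AGE_CLASSES)
    if bad:
        raise ValueError(f"unknown age classes {sorted(bad)}; expected {AGE_CLASSES}")
    meta = meta.copy()
    meta["date"] = pd.to_datetime(meta["date"])
    return meta


@dataclass
class FilterReport:
    """Sample-pair counts before/after the exclusion filters."""

    total_between_individual: int
    removed_immature_immature: int
    removed_mother_immature: int
    overlap_of_removals: int
    final: int
    final_mother_offspring: int

    def __post_init__(self) -> None:
        removed = (
            self.removed_immature_immature
            + self.removed_mother_immature
            - self.overlap_of_removals
        )
        if self.final != self.total_between_individual - removed:
            raise ValueError("filter report counts are inconsistent")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def build_dyads(
    meta: pd.DataFrame,
    similarities: dict[str, SimilarityMatrix],
    sri: SriMatrix,
    centroids: dict[str, tuple[float, float]],
    ped: PedigreeTable,
) -> pd.DataFrame:
    """One row per unordered between-individual sample pair, fully coded.

    ``similarities`` maps metric label -> SimilarityMatrix covering all
    samples in ``meta``. Raises if any individual is missing from the SRI
    matrix, centroids or pedigree (listing the gaps).
    """
    meta = validate_metadata(meta)
    inds = pd.unique(meta["individual_id"])
    gaps = {
        "sri": [i for i in inds if i not in sri.data.index],
        "centroids": [i for i in inds if i not in centroids],
        "pedigree": [i for i in inds if i not in ped.data.index],
    }
    gaps = {k: v for k, v in gaps.items() if v}
    if gaps:
        raise KeyError(f"individuals missing from auxiliary inputs: {gaps}")
    for label, sim in similarities.items():
        missing = set(meta["sample_id"]) - set(sim.data.index)
        if missing:
            raise KeyError(f"samples missing from {label} similarity: {sorted(missing)[:10]}")

    m = meta.reset_index(drop=True)
    n = len(m)
    ia, ib = np.triu_indices(n, k=1)
    between = m["individual_id"].to_numpy()[ia] != m["individual_id"].to_numpy()[ib]
    ia, ib = ia[between], ib[between]

    sid = m["sample_id"].to_numpy()
    iid = m["individual_id"].to_numpy()
    age = m["age_class"].to_numpy()
    sex = m["sex"].to_numpy()
    days = m["date"].to_numpy()

    rows = pd.DataFrame(
        {
            "sample_a": sid[ia],
            "sample_b": sid[ib],
            "individual_a": iid[ia],
            "individual_b": iid[ib],
            "age_class_a": age[ia],
            "age_class_b": age[ib],
        }
    )
    for label, sim in similarities.items():
        mat = sim.data.loc[sid, sid].to_numpy()
        rows[label] = mat[ia, ib]

    # individual-level covariates via a pair cache (few individuals, many samples)
    pair_cache: dict[tuple[str, str], tuple[int, float, float]] = {}

    def _ind_cov(a: str, b: str) -> tuple[int, float, float]:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = (
                mother_offspring(ped, *key),
                relatedness(ped, *key),
                spatial_distance(centroids[key[0]], centroids[key[1]]),
            )
        return pair_cache[key]

    cov = [_ind_cov(a, b) for a, b in zip(rows["individual_a"], rows["individual_b"])]
    rows["mo_status"] = [c[0] for c in cov]
    rows["relatedness"] = [c[1] for c in cov]
    rows["spatial_dist"] = [c[2] for c in cov]
    ai = sri.data.index.get_indexer(rows["individual_a"])
    bi = sri.data.columns.get_indexer(rows["individual_b"])
    rows["sri"] = sri.data.to_numpy()[ai, bi]
    rows["age_sim"] = (age[ia] == age[ib]).astype(int)
    rows["sex_sim"] = (sex[ia] == sex[ib]).astype(int)
    rows["interval_days"] = np.abs((days[ia] - days[ib]) / np.timedelta64(1, "D")).astype(int)

    # which member is the mother, for the mother-sampled-immature filter
    mom_is_a = []
    for a, b, mo in zip(rows["individual_a"], rows["individual_b"], rows["mo_status"]):
        if not mo:
            mom_is_a.append(pd.NA)
        else:
            mom_is_a.append(ped.parents(b)[0] == a)
    rows["mother_is_a"] = mom_is_a
    return rows


def apply_filters(rows: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop immature-immature pairs and mother-sampled-immature MO pairs."""
    imm_imm = (rows["age_class_a"] == "immature") & (rows["age_class_b"] == "immature")
    is_mo = rows["mo_status"] == 1
    mother_is_a = (rows["mother_is_a"] == True).to_numpy()  # noqa: E712 (NA -> False)
    mother_age = np.where(mother_is_a, rows["age_class_a"], rows["age_class_b"])
    mo_imm = is_mo & (mother_age == "immature")

    removed = imm_imm | mo_imm
    kept = rows[~removed].reset_index(drop=True)
    report = FilterReport(
        total_between_individual=len(rows),
        removed_immature_immature=int(imm_imm.sum()),
        removed_mother_immature=int(mo_imm.sum()),
        overlap_of_removals=int((imm_imm & mo_imm).sum()),
        final=len(kept),
        final_mother_offspring=int((kept["mo_status"] == 1).sum()),
    )
    # after filter (ii), a mixed-age MO pair always has the offspring immature
    mixed_mo = kept[(kept["mo_status"] == 1) & (kept["age_sim"] == 0)]
    off_age = np.where(mixed_mo["mother_is_a"].astype(bool), mixed_mo["age_class_b"], mixed_mo["age_class_a"])
    assert (off_age == "immature").all()
    return kept, report


@dataclass
class ScalingRecord:
    """Per-covariate (mean, sd) used for centring/scaling; sd=None if left raw."""

    params: dict[str, tuple[float, float]]

    def back_transform(self, col: str, values):
        mean, sd = self.params[col]
        return np.asarray(values) * sd + mean


def standardize_covariates(
    rows: pd.DataFrame, columns: tuple[str, ...] = CONTINUOUS_COVARIATES
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Centre and scale continuous covariates to unit SD (binary ones stay 0/1).

    Zero-variance columns are left unscaled with a warning.
    """
    out = rows.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        mean, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0:
            warnings.warn(f"covariate {col!r} has zero variance; left unscaled")
            continue
        out[col] = (x - mean) / sd
        params[col] = (mean, sd)
    return out, ScalingRecord(params)


def squeeze_response(y, n: int):
    """Smithson-Verkuilen compression of [0,1] similarities into (0,1).

    y' = (y * (n - 1) + 0.5) / n, with n the number of rows in the final
    dyad table. Needed because the Beta likelihood is defined on the open
    interval.
    """
    if n < 2:
        raise ValueError("squeeze requires n >= 2")
    return (np.asarray(y, dtype=float) * (n - 1) + 0.5) / n


def write_dyads_tsv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_dyads_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
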