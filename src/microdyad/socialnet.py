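"""Social network and space use from nightly PIT-tag logger detections.

A detection record says: individual X was logged at station L (coordinates
x, y) during night N, where a night is one 12-hour window (6pm-6am). Two
individuals are socially associated on a night if they were detected at the
same station that night.

Pairwise association uses an adjusted Simple Ratio Index that restricts the
tally to the nights within both individuals' observation lifespans (first to
last detection), so pairs whose monitoring periods barely overlap are not
diluted. Within that joint window:

    SRI(a, b) = (#nights a and b co-detected at the same station)
                / (#nights a or b was detected)

and 0 when the joint window is empty or neither was detected in it.
Co-detection requires the same station id; multiple hits of a pair at one
station in one night count once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOGGER_COLUMNS = ("individual_id", "location_id", "x", "y", "night")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOGGER_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"logger records missing columns: {missing}")
    if (records["night"] < 1).any():
        raise ValueError("night index must be >= 1")
    if not np.isfinite(records[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite logger coordinates")
    return records


@dataclass
class SriMatrix:
    """Symmetric individual x individual adjusted-SRI matrix."""

    data: pd.DataFrame

    @property
    def individuals(self) -> pd.Index:
        return self.data.index

    def pair(self, a: str, b: str) -> float:
        return float(self.data.at[a, b])


def _night_locations(records: pd.DataFrame) -> dict:
    """individual -> {night -> set of location ids}."""
    out: dict = {}
    for ind, grp in records.groupby("individual_id"):
        nights: dict = {}
        for night, locs in grp.groupby("night")["location_id"]:
            nights[int(night)] = set(locs)
        out[ind] = nights
    return out


def _sri_from_nightmaps(na: dict, nb: dict) -> float:
    fa, la = min(na), max(na)
    fb, lb = min(nb), max(nb)
    lo, hi = max(fa, fb), min(la, lb)
    if lo > hi:
        return 0.0
    x = d = 0
    for night in range(lo, hi + 1):
        sa = na.get(night)
        sb = nb.get(night)
        if sa or sb:
            d += 1
            if sa and sb and sa & sb:
                x += 1
    return x / d if d else 0.0


def adjusted_sri(records: pd.DataFrame, a: str, b: str) -> float:
    """Adjusted SRI for one pair (see module docstring for the definition)."""
    _validate_records(records)
    maps = _night_locations(records[records["individual_id"].isin([a, b])])
    for ind in (a, b):
        if ind not in maps:
            raise KeyError(f"no logger records for individual {ind!r}")
    return _sri_from_nightmaps(maps[a], maps[b])


def sri_matrix(records: pd.DataFrame, individuals=None) -> SriMatrix:
    """Adjusted SRI for all pairs of detected individuals (or a given ordering)."""
    _validate_records(records)
    maps = _night_locations(records)
    if individuals is None:
        individuals = sorted(maps)
    else:
        gaps = [i for i in individuals if i not in maps]
        if gaps:
            raise KeyError(f"no logger records for individuals: {gaps}")
    n = len(individuals)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = _sri_from_nightmaps(maps[individuals[i]], maps[individuals[j]])
            out[i, j] = out[j, i] = v
    return SriMatrix(pd.DataFrame(out, index=list(individuals), columns=list(individuals)))


def spatial_centroid(records: pd.DataFrame, individual: str) -> tuple[float, float]:
    """Arithmetic mean of all detection coordinates (each record counts once)."""
    sub = records[records["individual_id"] == individual]
    if sub.empty:
        raise KeyError(f"no logger records for individual {individual!r}")
    return float(sub["x"].mean()), float(sub["y"].mean())


def all_centroids(records: pd.DataFrame) -> dict:
    _validate_records(records)
    g = records.groupby("individual_id")[["x", "y"]].mean()
    return {ind: (float(r["x"]), float(r["y"])) for ind, r in g.iterrows()}


def spatial_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Euclidean distance between two centroids, in metres."""
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def read_logger_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["night"] = df["night"].astype(int)
    return _validate_records(df)


def write_sri_tsv(sri: SriMatrix, path) -> None:
    sri.data.to_csv(path, sep="\t", index_label="individual_id")


def read_sri_tsv(path) -> SriMatrix:
    return SriMatrix(pd.read_csv(path, sep="\t", index_col=0))
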