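import pandas as pd
import pytest

from microdyad.pedigree import PedigreeTable
from microdyad.taxa import AsvTable, TaxonomyTable


@pytest.fixture
def toy_pedigree() -> PedigreeTable:
    """Five individuals: mother M1 with offspring O1 and O2 (different
    fathers known/unknown), father F1 of O1, and an unrelated U1."""
    data = pd.DataFrame(
        {
            "mother_id": [None, None, "M1", "M1", None],
            "father_id": [None, None, "F1", None, None],
            "sex": ["F", "M", "M", "F", "M"],
        },
        index=pd.Index(["M1", "F1", "O1", "O2", "U1"], name="individual_id"),
    )
    return PedigreeTable(data)


@pytest.fixture
def toy_asv() -> AsvTable:
    data = pd.DataFrame(
        {
            "ASV1": [5.0, 0.0, 2.0],
            "ASV2": [3.0, 4.0, 0.0],
            "ASV3": [0.0, 1.0, 7.0],
        },
        index=["s1", "s2", "s3"],
    )
    return AsvTable(data, mode="counts")


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    data = pd.DataFrame(
        {
            "kingdom": ["k__Bacteria"] * 3,
            "phylum": ["p__Bacteroidota", "p__Cyanobacteria", "p__Firmicutes"],
            "class": [pd.NA] * 3,
            "order": [pd.NA] * 3,
            "family": ["f__Muribaculaceae", pd.NA, "f__Lachnospiraceae"],
            "genus": [pd.NA] * 3,
        },
        index=pd.Index(["ASV1", "ASV2", "ASV3"], name="asv_id"),
    )
    return TaxonomyTable(data)


@pytest.fixture
def toy_loggers() -> pd.DataFrame:
    """Two individuals with overlapping lifespans: a detected nights 1-6,
    b nights 4-10; co-located nights 4 and 5; night 6 only a."""
    rows = []
    for night in (1, 2, 3, 4, 5, 6):
        rows.append(("a", "L1", 0.0, 0.0, night))
    for night in (4, 5):
        rows.append(("b", "L1", 0.0, 0.0, night))
    for night in (7, 8, 9, 10):
        rows.append(("b", "L2", 10.0, 0.0, night))
    return pd.DataFrame(rows, columns=["individual_id", "location_id", "x", "y", "night"])


def brute_force_jaccard(a, b) -> float:
    sa = {i for i, v in enumerate(a) if v > 0}
    sb = {i for i, v in enumerate(b) if v > 0}
    return len(sa & sb) / len(sa | sb)


def brute_force_braycurtis(a, b) -> float:
    num = sum(abs(x - y) for x, y in zip(a, b))
    den = sum(x + y for x, y in zip(a, b))
    return 1.0 - num / den


def brute_force_sri(records: pd.DataFrame, a: str, b: str) -> float:
    """Night-by-night tally, written independently of the library's version."""
    ra = records[records["individual_id"] == a]
    rb = records[records["individual_id"] == b]
    lo = max(ra["night"].min(), rb["night"].min())
    hi = min(ra["night"].max(), rb["night"].max())
    x = d = 0
    for night in range(int(lo), int(hi) + 1):
        la = set(ra.loc[ra["night"] == night, "location_id"])
        lb = set(rb.loc[rb["night"] == night, "location_id"])
        if la or lb:
            d += 1
        if la & lb:
            x += 1
    return x / d if d else 0.0
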