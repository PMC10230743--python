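"""ASV-table handling and pairwise microbiota similarity.

The abundance table is the substrate for everything downstream: it is loaded
as samples x ASVs, cleaned (non-gut lineages out, singletons out), normalised
to proportional abundance per sample, and turned into pairwise similarity
matrices (Jaccard on presence/absence, Bray-Curtis on proportions).

The pipeline applies the filters in a fixed, logged order:
non-gut removal -> singleton removal -> proportional normalisation.
Jaccard is invariant to the normalisation step since the presence pattern is
unchanged by a positive per-row rescaling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: default non-gut lineages removed before analysis
DEFAULT_NONGUT = ("Cyanobacteria", "Mitochondria")

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")


def strip_rank_prefix(label: str) -> str:
    """Remove a GreenGenes-style rank prefix (``f__Muribaculaceae`` -> ``Muribaculaceae``)."""
    return _PREFIX_RE.sub("", label).strip()


@dataclass
class AsvTable:
    """Samples x ASVs abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id, columns are ASV ids. Entries are
        nonnegative counts or proportions.
    mode:
        ``"counts"`` or ``"proportions"``.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative abundances in ASV table")
        if self.mode == "proportions":
            sums = self.data.sum(axis=1).to_numpy()
            nonempty = sums > 0
            if nonempty.any() and not np.allclose(sums[nonempty], 1.0, atol=1e-9):
                raise ValueError("proportion rows must sum to 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def asv_ids(self) -> pd.Index:
        return self.data.columns

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (abundance strictly > 0)."""
        return self.data > 0


@dataclass
class TaxonomyTable:
    """ASV id -> six-rank lineage (kingdom..genus); any rank may be NA."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")

    def require_cover(self, asv: AsvTable) -> None:
        gaps = asv.asv_ids.difference(self.data.index)
        if len(gaps):
            raise KeyError(f"taxonomy does not cover ASVs: {sorted(gaps)[:10]}")

    def family_of(self) -> pd.Series:
        """Family label per ASV with rank prefixes stripped; NA where unassigned."""
        fam = self.data["family"]
        out = fam.map(lambda v: strip_rank_prefix(v) if isinstance(v, str) else v)
        return out.replace("", pd.NA)

    def assigned_families(self) -> list[str]:
        fam = self.family_of().dropna()
        return sorted(fam.unique())


@dataclass
class SimilarityMatrix:
    """Symmetric sample x sample similarity matrix with a metric label."""

    data: pd.DataFrame
    metric: str

    def pair(self, a: str, b: str) -> float:
        return float(self.data.at[a, b])


# ---------------------------------------------------------------------------
# filters


def filter_nongut(
    asv: AsvTable, tax: TaxonomyTable, excluded: tuple[str, ...] = DEFAULT_NONGUT
) -> AsvTable:
    """Drop ASVs whose lineage contains any excluded label at any rank.

    Matching is case-insensitive and ignores rank prefixes. An empty
    exclusion list is a no-op.
    """
    if not excluded:
        return asv
    tax.require_cover(asv)
    targets = {e.lower() for e in excluded}
    lin = tax.data.loc[asv.asv_ids, list(RANKS)]

    def _hit(row) -> bool:
        for v in row:
            if isinstance(v, str) and strip_rank_prefix(v).lower() in targets:
                return True
        return False

    bad = lin.apply(_hit, axis=1)
    keep = asv.asv_ids[~bad.to_numpy()]
    return replace(asv, data=asv.data[keep])


def remove_singletons(asv: AsvTable, definition: str = "total_count") -> AsvTable:
    """Remove singleton ASVs from a counts-mode table.

    ``definition="total_count"`` (default): total count over all samples <= 1.
    ``definition="single_sample"``: present in exactly one sample.
    """
    if asv.mode != "counts":
        raise ValueError("singleton removal requires a counts-mode table")
    if definition == "total_count":
        keep = asv.data.sum(axis=0) > 1
    elif definition == "single_sample":
        keep = (asv.data > 0).sum(axis=0) != 1
    else:
        raise ValueError(f"unknown singleton definition {definition!r}")
    return replace(asv, data=asv.data.loc[:, keep])


def normalize_proportions(asv: AsvTable) -> AsvTable:
    """Divide each sample row by its total; switch mode to proportions."""
    if asv.mode != "counts":
        raise ValueError("normalisation expects a counts-mode table")
    sums = asv.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample rows: {list(zero.index)}")
    return AsvTable(asv.data.div(sums, axis=0), mode="proportions")


# ---------------------------------------------------------------------------
# pairwise similarity


def jaccard_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Proportion of ASVs shared: |present(a) & present(b)| / |present(a) | present(b)|."""
    pa = np.asarray(a) > 0
    pb = np.asarray(b) > 0
    union = int(np.logical_or(pa, pb).sum())
    if union == 0:
        raise ValueError("Jaccard undefined: both samples empty")
    inter = int(np.logical_and(pa, pb).sum())
    return inter / union


def braycurtis_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """1 - sum|a-b| / sum(a+b) on relative abundances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = float((a + b).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined: both samples empty")
    return 1.0 - float(np.abs(a - b).sum()) / denom


def exclude_family(asv: AsvTable, tax: TaxonomyTable, family: str) -> AsvTable:
    """Remove every ASV assigned to ``family`` (prefix-stripped exact match).

    ASVs with an unassigned family are never removed. Excluding a family
    absent from the taxonomy returns the table unchanged.
    """
    tax.require_cover(asv)
    fam = tax.family_of().reindex(asv.asv_ids)
    target = strip_rank_prefix(family)
    keep = asv.asv_ids[(fam != target) | fam.isna()]
    return replace(asv, data=asv.data[keep])


def similarity_matrix(asv: AsvTable, metric: str) -> SimilarityMatrix:
    """All-pairs similarity for the chosen metric (``jaccard`` or ``braycurtis``)."""
    x = asv.data.to_numpy(dtype=float)
    empty = x.sum(axis=1) == 0
    if empty.any():
        names = list(asv.sample_ids[empty])
        raise ValueError(f"similarity undefined for empty samples: {names}")
    if metric == "jaccard":
        d = _ssd.squareform(_ssd.pdist(x > 0, metric="jaccard"))
    elif metric == "braycurtis":
        if asv.mode != "proportions":
            raise ValueError("Bray-Curtis similarity requires a proportions-mode table")
        d = _ssd.squareform(_ssd.pdist(x, metric="braycurtis"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sim = 1.0 - d
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(
        pd.DataFrame(sim, index=asv.sample_ids, columns=asv.sample_ids), metric=metric
    )


# ---------------------------------------------------------------------------
# IO


def read_asv_tsv(path, orientation: str = "samples_as_rows", mode: str = "counts") -> AsvTable:
    """Read an ASV table from TSV. First column holds row ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "asvs_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return AsvTable(df.astype(float), mode=mode)


def read_asv_biom(path, mode: str = "counts") -> AsvTable:
    """Read a BIOM 2.1 (HDF5) table: observations x samples CSR -> samples x ASVs."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        obs_ids = [s.decode() if isinstance(s, bytes) else s for s in f["observation/ids"][:]]
        samp_ids = [s.decode() if isinstance(s, bytes) else s for s in f["sample/ids"][:]]
        g = f["observation/matrix"]
        mat = csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(obs_ids), len(samp_ids)),
        )
    df = pd.DataFrame(mat.T.toarray(), index=samp_ids, columns=obs_ids, dtype=float)
    return AsvTable(df, mode=mode)


def read_taxonomy_tsv(path) -> TaxonomyTable:
    """Read taxonomy from TSV: either split rank columns or a 'Taxon' lineage string."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = {c.lower(): c for c in df.columns}
    if all(r in cols for r in RANKS):
        out = df.rename(columns={cols[r]: r for r in RANKS})[list(RANKS)]
    else:
        lineage_col = next(
            (c for c in df.columns if c.lower() in ("taxon", "taxonomy", "lineage")), None
        )
        if lineage_col is None:
            raise ValueError("taxonomy TSV needs rank columns or a Taxon/lineage column")
        parts = df[lineage_col].str.split(";", expand=True).reindex(columns=range(6))
        parts = parts.apply(lambda s: s.str.strip())
        parts.columns = list(RANKS)
        out = parts
    return TaxonomyTable(out.where(out.notna() & (out != ""), pd.NA))


def write_asv_tsv(asv: AsvTable, path) -> None:
    asv.data.to_csv(path, sep="\t", index_label="sample_id")


def write_similarity_tsv(sim: SimilarityMatrix, path) -> None:
    sim.data.to_csv(path, sep="\t", index_label=sim.metric)
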