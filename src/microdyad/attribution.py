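"""Leave-one-bacterial-family-out attribution of the maternal signal.

For each bacterial family with assigned ASVs, the Jaccard similarity is
recomputed with that family's ASVs removed, the dyad table is rebuilt under
the same exclusion filters, and the interaction model (mother-offspring
status x age-class similarity) is refit with a reduced sampler. The change
(delta) in the mother-offspring main effect and in the interaction, relative
to the full model, quantifies how much of each signal that family carries:
a strongly maternally-transmitted family shows the most negative delta on
the main effect and the largest positive delta on the (negative)
interaction when dropped.

A companion diagnostic correlates each delta with the family's (logged) ASV
richness: a family whose influence merely reflects how many ASVs it removes
from the metric would sit on that trend, whereas a genuinely
disproportionate family (the *Muribaculaceae* pattern) stands off it.

ASVs with unassigned family are never dropped; they are reported as an
"Unassigned" pseudo-family row (not scanned). Per-family fits use seeds
derived as base seed + family index, so the scan is reproducible and
parallelisable per family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dyads import apply_filters, build_dyads, squeeze_response, standardize_covariates
from .model import ModelSpec, SamplerSettings, fit_beta_mm, summarize
from .pedigree import PedigreeTable
from .socialnet import SriMatrix
from .taxa import AsvTable, TaxonomyTable, exclude_family, similarity_matrix

FULL_MODEL_LABEL = "(full model)"

INTERACTION_SPEC = ModelSpec(
    response="jaccard",
    interactions=(("mo_status", "age_sim"), ("sri", "age_sim")),
)


def _fit_effects(
    asv: AsvTable,
    meta: pd.DataFrame,
    sri: SriMatrix,
    centroids: dict,
    ped: PedigreeTable,
    settings: SamplerSettings,
) -> dict:
    sim = similarity_matrix(asv, "jaccard")
    rows = build_dyads(meta, {"jaccard": sim}, sri, centroids, ped)
    rows, report = apply_filters(rows)
    rows["jaccard"] = squeeze_response(rows["jaccard"], len(rows))
    rows, _ = standardize_covariates(rows)
    fit = fit_beta_mm(rows, INTERACTION_SPEC, settings)
    summ = summarize(fit)

    def grab(term):
        r = summ.loc[term]
        return {
            "mean": float(r["estimate"]),
            "lo": float(r["q2.5"]),
            "hi": float(r["q97.5"]),
            "significant": bool(r["significant"]),
        }

    return {
        "mo": grab("mo_status"),
        "inter": grab("mo_status:age_sim"),
        "n_dyads": len(rows),
    }


def family_exclusion_scan(
    asv: AsvTable,
    tax: TaxonomyTable,
    meta: pd.DataFrame,
    sri: SriMatrix,
    centroids: dict,
    ped: PedigreeTable,
    settings: SamplerSettings | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Refit the interaction model once per assigned family, dropping it.

    Returns one row per family plus a reference row for the full model
    (family = ``"(full model)"``). Families whose exclusion would empty any
    sample are flagged and skipped. Deltas are excluded-model effect minus
    full-model effect.
    """
    settings = settings or SamplerSettings.reduced()
    fam = tax.family_of().reindex(asv.asv_ids)
    families = sorted(fam.dropna().unique())
    if len(families) < 2:
        raise ValueError("need at least two assigned families to scan")

    from dataclasses import replace as _dc_replace

    full = _fit_effects(asv, meta, sri, centroids, ped,
                        _dc_replace(settings, seed=base_seed))
    rows = [
        {
            "family": FULL_MODEL_LABEL,
            "n_asvs": int(fam.notna().sum()),
            "log_n_asvs": float(np.log(max(int(fam.notna().sum()), 1))),
            "mo_mean": full["mo"]["mean"],
            "mo_lo": full["mo"]["lo"],
            "mo_hi": full["mo"]["hi"],
            "mo_significant": full["mo"]["significant"],
            "inter_mean": full["inter"]["mean"],
            "inter_lo": full["inter"]["lo"],
            "inter_hi": full["inter"]["hi"],
            "inter_significant": full["inter"]["significant"],
            "delta_mo": 0.0,
            "delta_inter": 0.0,
            "n_dyads": full["n_dyads"],
            "skipped": False,
            "skip_reason": "",
        }
    ]
    n_unassigned = int(fam.isna().sum())

    for k, family in enumerate(families, start=1):
        n_asvs = int((fam == family).sum())
        reduced = exclude_family(asv, tax, family)
        row = {
            "family": family,
            "n_asvs": n_asvs,
            "log_n_asvs": float(np.log(n_asvs)),
            "skipped": False,
            "skip_reason": "",
        }
        emptied = reduced.data.sum(axis=1) == 0
        if emptied.any():
            row.update(
                skipped=True,
                skip_reason=f"exclusion empties samples: {list(reduced.sample_ids[emptied])[:5]}",
                **{c: np.nan for c in ("mo_mean", "mo_lo", "mo_hi", "inter_mean",
                                        "inter_lo", "inter_hi", "delta_mo", "delta_inter")},
                mo_significant=pd.NA, inter_significant=pd.NA,
            )
            rows.append(row)
            continue
        res = _fit_effects(reduced, meta, sri, centroids, ped,
                           _dc_replace(settings, seed=base_seed + k))
        row.update(
            mo_mean=res["mo"]["mean"], mo_lo=res["mo"]["lo"], mo_hi=res["mo"]["hi"],
            mo_significant=res["mo"]["significant"],
            inter_mean=res["inter"]["mean"], inter_lo=res["inter"]["lo"],
            inter_hi=res["inter"]["hi"], inter_significant=res["inter"]["significant"],
            delta_mo=res["mo"]["mean"] - full["mo"]["mean"],
            delta_inter=res["inter"]["mean"] - full["inter"]["mean"],
            n_dyads=res["n_dyads"],
        )
        rows.append(row)

    if n_unassigned:
        rows.append(
            {
                "family": "Unassigned",
                "n_asvs": n_unassigned,
                "log_n_asvs": float(np.log(n_unassigned)),
                "skipped": True,
                "skip_reason": "unassigned family is never scanned",
                **{c: np.nan for c in ("mo_mean", "mo_lo", "mo_hi", "inter_mean",
                                        "inter_lo", "inter_hi", "delta_mo", "delta_inter")},
                "mo_significant": pd.NA, "inter_significant": pd.NA,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RichnessDiagnostic:
    """Rank correlation between family richness and scan deltas."""

    spearman_mo: float
    spearman_inter: float
    p_mo: float
    p_inter: float
    top_family: str
    richest_family: str
    top_is_richest: bool


def richness_vs_effect(scan: pd.DataFrame) -> RichnessDiagnostic:
    """Is a family's influence on the maternal signal explained by its richness?

    Correlates log ASV richness with the per-family deltas (Spearman) and
    flags whether the family with the strongest attenuation of the
    mother-offspring main effect is also the richest — the check that
    disproportionate influence is not a richness artefact.
    """
    sub = scan[(scan["family"] != FULL_MODEL_LABEL) & (~scan["skipped"].astype(bool))]
    if len(sub) < 3:
        raise ValueError("need at least 3 scanned families")
    if sub["delta_mo"].nunique() == 1:
        rho_mo, p_mo = 0.0, 1.0
    else:
        rho_mo, p_mo = spearmanr(sub["log_n_asvs"], sub["delta_mo"])
    if sub["delta_inter"].nunique() == 1:
        rho_in, p_in = 0.0, 1.0
    else:
        rho_in, p_in = spearmanr(sub["log_n_asvs"], sub["delta_inter"])
    top = sub.loc[sub["delta_mo"].idxmin(), "family"]
    richest = sub.loc[sub["n_asvs"].idxmax(), "family"]
    return RichnessDiagnostic(
        spearman_mo=float(rho_mo),
        spearman_inter=float(rho_in),
        p_mo=float(p_mo),
        p_inter=float(p_in),
        top_family=str(top),
        richest_family=str(richest),
        top_is_richest=top == richest,
    )


def write_scan_tsv(scan: pd.DataFrame, path) -> None:
    scan.to_csv(path, sep="\t", index=False)


def plot_scan(scan: pd.DataFrame, path_main, path_inter) -> None:
    """Effect-vs-log-richness panels mirroring the scan's standard display."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = scan[(scan["family"] != FULL_MODEL_LABEL) & (~scan["skipped"].astype(bool))]
    full = scan[scan["family"] == FULL_MODEL_LABEL].iloc[0]
    for col, lo, hi, ref, path in (
        ("mo_mean", "mo_lo", "mo_hi", full["mo_mean"], path_main),
        ("inter_mean", "inter_lo", "inter_hi", full["inter_mean"], path_inter),
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.errorbar(
            sub["log_n_asvs"], sub[col],
            yerr=[sub[col] - sub[lo], sub[hi] - sub[col]],
            fmt="o", ms=4, lw=0.8, capsize=2,
        )
        ax.axhline(ref, color="red", lw=1, label="full model")
        ax.axhline(0, color="grey", lw=0.5, ls=":")
        ax.set_xlabel("log(number of ASVs in dropped family)")
        ax.set_ylabel(col)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
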