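"""End-to-end orchestration: inputs -> filters -> similarity -> dyads -> fits.

The pipeline fixes the filter order (non-gut removal -> singleton removal ->
proportional normalisation), builds Jaccard (presence) and optionally
Bray-Curtis (proportions) similarity, assembles and filters the dyad table,
squeezes the response into (0,1), standardizes continuous covariates, and
fits two models: the main-effects model and the interaction model
(mother-offspring x age-class similarity, SRI x age-class similarity).
Every run writes a provenance JSON (config hash, seeds, package and library
versions) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__
from .attribution import family_exclusion_scan, richness_vs_effect, write_scan_tsv
from .dyads import (
    apply_filters,
    build_dyads,
    read_metadata_csv,
    squeeze_response,
    standardize_covariates,
    write_dyads_tsv,
)
from .mantel import mantel
from .model import (
    ModelSpec,
    SamplerSettings,
    check_convergence,
    fit_beta_mm,
    stratum_effect_from_fit,
    summarize,
    write_summary_tsv,
)
from .pedigree import mother_offspring, read_pedigree_csv
from .socialnet import all_centroids, read_logger_csv, sri_matrix, write_sri_tsv
from .synthetic import SimParams, simulate_study, write_study
from .taxa import (
    DEFAULT_NONGUT,
    filter_nongut,
    normalize_proportions,
    read_asv_biom,
    read_asv_tsv,
    read_taxonomy_tsv,
    remove_singletons,
    similarity_matrix,
    write_similarity_tsv,
)

MAIN_SPEC = ModelSpec(response="jaccard")
INTERACTION_SPEC = ModelSpec(
    response="jaccard", interactions=(("mo_status", "age_sim"), ("sri", "age_sim"))
)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    if ("inputs" in cfg) == ("simulate" in cfg):
        raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
    metric = cfg.get("metric", "jaccard")
    if metric not in ("jaccard", "braycurtis"):
        raise ValueError(f"unknown metric label {metric!r}")
    if "inputs" in cfg:
        needed = {"asv", "taxonomy", "metadata", "pedigree", "loggers"}
        missing = needed - set(cfg["inputs"])
        if missing:
            raise ValueError(f"config inputs missing: {sorted(missing)}")
        for k, p in cfg["inputs"].items():
            if not os.path.exists(p):
                raise FileNotFoundError(f"input {k}: {p}")


def _provenance(cfg: dict, seed: int) -> dict:
    import numpy
    import scipy

    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "microdyad": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "filter_order": "non-gut removal -> singleton removal -> proportional normalisation",
        "squeeze": "smithson-verkuilen, applied after filtering with the final row count",
        "standardize": "continuous covariates centred/scaled to unit SD (default on)",
    }


def run_pipeline(config, outdir=None) -> dict:
    """Run the whole analysis from a config path or dict; returns artifacts.

    The returned dict carries the in-memory objects (dyad rows, fits,
    summaries, reports); files are written under ``outdir`` (or the config's
    ``output_dir``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    _validate_config(cfg)
    outdir = outdir or cfg.get("output_dir", "microdyad_out")
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    if "simulate" in cfg:
        params = SimParams(**{**cfg["simulate"], "seed": seed})
        study = simulate_study(params)
        write_study(study, os.path.join(outdir, "fixture"))
        asv, tax = study.asv, study.taxonomy
        meta = study.metadata
        ped = study.pedigree
        logs = study.loggers
    else:
        paths = cfg["inputs"]
        if str(paths["asv"]).endswith(".biom"):
            asv = read_asv_biom(paths["asv"])
        else:
            asv = read_asv_tsv(paths["asv"])
        tax = read_taxonomy_tsv(paths["taxonomy"])
        meta = read_metadata_csv(paths["metadata"])
        ped = read_pedigree_csv(paths["pedigree"])
        logs = read_logger_csv(paths["loggers"])

    # fixed, logged filter order
    excluded = tuple(cfg.get("nongut_taxa", DEFAULT_NONGUT))
    counts = remove_singletons(filter_nongut(asv, tax, excluded))
    props = normalize_proportions(counts)

    sims = {"jaccard": similarity_matrix(counts, "jaccard")}
    metric = cfg.get("metric", "jaccard")
    if metric == "braycurtis":
        sims["braycurtis"] = similarity_matrix(props, "braycurtis")
    for label, sim in sims.items():
        write_similarity_tsv(sim, os.path.join(outdir, f"similarity_{label}.tsv"))

    sri = sri_matrix(logs, individuals=sorted(pd.unique(meta["individual_id"])))
    write_sri_tsv(sri, os.path.join(outdir, "sri.tsv"))
    centroids = all_centroids(logs)

    rows = build_dyads(meta, sims, sri, centroids, ped)
    rows, report = apply_filters(rows)
    report.to_json(os.path.join(outdir, "filter_report.json"))
    for label in sims:
        rows[label] = squeeze_response(rows[label], len(rows))
    if cfg.get("standardize", True):
        rows, scaling = standardize_covariates(rows)
    write_dyads_tsv(rows, os.path.join(outdir, "dyads.tsv"))

    if not cfg.get("fit", True):
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(_provenance(cfg, seed), fh, indent=2)
        return {
            "dyads": rows,
            "filter_report": report,
            "fits": {},
            "summaries": {},
            "convergence": {},
            "outdir": outdir,
        }

    sampler = SamplerSettings(**{**cfg.get("sampler", {}), "seed": seed})
    response = metric
    specs = {
        "main": ModelSpec(response=response),
        "interaction": ModelSpec(
            response=response,
            interactions=(("mo_status", "age_sim"), ("sri", "age_sim")),
        ),
    }
    fits, summaries, convergence = {}, {}, {}
    for name, spec in specs.items():
        fit = fit_beta_mm(rows, spec, sampler)
        fits[name] = fit
        summaries[name] = summarize(fit)
        write_summary_tsv(summaries[name], os.path.join(outdir, f"summary_{name}.tsv"))
        conv = check_convergence(
            fit, cfg.get("rhat_threshold", 1.05),
            plot_dir=os.path.join(outdir, f"traces_{name}"),
        )
        convergence[name] = conv
        if not conv.passed:
            raise RuntimeError(
                f"model {name!r} failed convergence: Rhat > {conv.threshold} for {conv.failing}"
            )

    strata = {
        "mo_adult_immature": stratum_effect_from_fit(fits["interaction"], "mo_status", "age_sim", 0),
        "mo_adult_adult": stratum_effect_from_fit(fits["interaction"], "mo_status", "age_sim", 1),
    }
    with open(os.path.join(outdir, "stratum_effects.json"), "w") as fh:
        json.dump(strata, fh, indent=2)

    # Mantel check: MO status vs SRI at the individual level
    inds = list(sri.individuals)
    mo_mat = pd.DataFrame(0.0, index=inds, columns=inds)
    for i, a in enumerate(inds):
        for b in inds[i + 1:]:
            v = float(mother_offspring(ped, a, b))
            mo_mat.at[a, b] = mo_mat.at[b, a] = v
    if mo_mat.to_numpy().sum() > 0:
        r, p = mantel(mo_mat, sri.data, n_perm=int(cfg.get("mantel_permutations", 9999)),
                      seed=seed)
        mantel_result = {"r": r, "p": p}
    else:
        mantel_result = {"r": None, "p": None, "note": "no mother-offspring pairs"}
    with open(os.path.join(outdir, "mantel.json"), "w") as fh:
        json.dump(mantel_result, fh, indent=2)

    scan = None
    if cfg.get("scan", False):
        scan = family_exclusion_scan(
            counts, tax, meta, sri, centroids, ped,
            SamplerSettings.reduced(seed), base_seed=seed,
        )
        write_scan_tsv(scan, os.path.join(outdir, "family_scan.tsv"))
        diag = richness_vs_effect(scan)
        with open(os.path.join(outdir, "richness_diagnostic.json"), "w") as fh:
            json.dump(asdict(diag), fh, indent=2)

    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(_provenance(cfg, seed), fh, indent=2)

    return {
        "dyads": rows,
        "filter_report": report,
        "fits": fits,
        "summaries": summaries,
        "convergence": convergence,
        "stratum_effects": strata,
        "mantel": mantel_result,
        "scan": scan,
        "outdir": outdir,
    }
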