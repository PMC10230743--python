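import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from microdyad.pedigree import mother_offspring
from microdyad.socialnet import sri_matrix
from microdyad.synthetic import (
    SimParams,
    simulate_logger_records,
    simulate_microbiota,
    simulate_population,
    simulate_study,
    write_study,
)
from microdyad.taxa import jaccard_similarity


SMALL = dict(n_individuals=24, n_mothers=3, litter_size_mean=2.0, n_families=8,
             asvs_per_family_mean=6.0, samples_per_individual=2.0, n_nights=90)


def _mo_and_unrelated_sims(study, age_filter=None):
    """Jaccard of mother-offspring vs unrelated between-individual sample pairs."""
    meta = study.metadata
    ped = study.pedigree
    presence = study.asv.data.to_numpy() > 0
    pos = {s: k for k, s in enumerate(study.asv.data.index)}
    ind_of = dict(zip(meta["sample_id"], meta["individual_id"]))
    age_of = dict(zip(meta["sample_id"], meta["age_class"]))
    mo_vals, un_vals = [], []
    for sa, sb in itertools.combinations(meta["sample_id"], 2):
        ia, ib = ind_of[sa], ind_of[sb]
        if ia == ib:
            continue
        if age_filter and age_filter not in (age_of[sa], age_of[sb]):
            continue
        a, b = presence[pos[sa]], presence[pos[sb]]
        if not (a.any() or b.any()):
            continue
        j = jaccard_similarity(a, b)
        if mother_offspring(ped, ia, ib):
            mo_vals.append(j)
        else:
            un_vals.append(j)
    return np.array(mo_vals), np.array(un_vals)


class TestPopulation:
    def test_seeded_runs_identical(self):
        a = simulate_study(SimParams(seed=7, **SMALL))
        b = simulate_study(SimParams(seed=7, **SMALL))
        pd.testing.assert_frame_equal(a.population.individuals, b.population.individuals)
        pd.testing.assert_frame_equal(a.loggers, b.loggers)
        pd.testing.assert_frame_equal(a.asv.data, b.asv.data)
        pd.testing.assert_frame_equal(a.sri.data, b.sri.data)

    def test_no_mothers_no_mo_pairs(self):
        pop = simulate_population(SimParams(n_individuals=12, n_mothers=0, seed=1))
        assert pop.individuals["mother_id"].isna().all()
        ped = pop.pedigree()
        inds = list(pop.individuals["individual_id"])
        assert all(
            mother_offspring(ped, a, b) == 0 for a, b in itertools.combinations(inds, 2)
        )

    def test_realised_litter_mean_matches_distribution(self):
        """1 + Poisson(mean-1) litters: 6 mothers x mean 3 -> ~18 offspring."""
        counts = []
        for seed in range(200):
            pop = simulate_population(
                SimParams(n_individuals=60, n_mothers=6, litter_size_mean=3.0, seed=seed)
            )
            counts.append(pop.individuals["mother_id"].notna().sum())
        assert np.mean(counts) == pytest.approx(18.0, abs=0.75)

    def test_mothers_are_recorded_females_with_offspring(self):
        pop = simulate_population(SimParams(seed=3, **SMALL))
        moms = set(pop.individuals["mother_id"].dropna())
        assert len(moms) == SMALL["n_mothers"]
        sexes = pop.individuals.set_index("individual_id").loc[sorted(moms), "sex"]
        assert (sexes == "F").all()

    def test_homes_inside_arena(self):
        p = SimParams(seed=5, **SMALL)
        pop = simulate_population(p)
        assert pop.individuals[["home_x", "home_y"]].to_numpy().min() >= 0
        assert pop.individuals[["home_x", "home_y"]].to_numpy().max() <= p.arena_size

    def test_immature_precedes_adult_within_individual(self):
        pop = simulate_population(SimParams(seed=11, **SMALL))
        for _, grp in pop.samples.sort_values("day").groupby("individual_id"):
            ages = list(grp["age_class"])
            if "adult" in ages and "immature" in ages:
                assert ages.index("adult") > max(
                    i for i, a in enumerate(ages) if a == "immature"
                )

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="n_individuals"):
            SimParams(n_individuals=10, n_mothers=5, litter_size_mean=3.0)
        with pytest.raises(ValueError, match="detection_rate"):
            SimParams(detection_rate=0.0)
        with pytest.raises(ValueError, match="adult_decay"):
            SimParams(adult_decay=1.5)


class TestLoggers:
    def test_one_logger_full_detection_gives_sri_one(self):
        p = SimParams(n_individuals=10, n_mothers=0, n_loggers=1, detection_rate=1.0,
                      n_nights=30, seed=2)
        pop = simulate_population(p)
        logs = simulate_logger_records(pop, p)
        sri = sri_matrix(logs)
        off_diag = sri.data.to_numpy()[~np.eye(len(sri.data), dtype=bool)]
        assert np.allclose(off_diag, 1.0)

    def test_records_within_study_and_near_home(self):
        p = SimParams(seed=4, **SMALL)
        pop = simulate_population(p)
        logs = simulate_logger_records(pop, p)
        assert logs["night"].between(1, p.n_nights).all()
        assert set(logs["individual_id"]) == set(pop.individuals["individual_id"])

    def test_codetection_falls_with_home_distance(self):
        """Averaged over seeds, SRI decreases with home-centre distance."""
        rhos = []
        for seed in range(25):
            p = SimParams(n_individuals=16, n_mothers=0, n_nights=60, seed=seed)
            pop = simulate_population(p)
            logs = simulate_logger_records(pop, p)
            sri = sri_matrix(logs, individuals=list(pop.individuals["individual_id"]))
            homes = pop.individuals.set_index("individual_id")[["home_x", "home_y"]]
            dists, sris = [], []
            for a, b in itertools.combinations(homes.index, 2):
                d = np.hypot(*(homes.loc[a] - homes.loc[b]))
                dists.append(d)
                sris.append(sri.data.at[a, b])
            rho, _ = spearmanr(dists, sris)
            rhos.append(rho)
        assert np.mean(rhos) < -0.3


class TestMicrobiota:
    def test_null_effects_mo_pairs_indistinguishable(self):
        """With no planted transmission, MO and unrelated dyads share alike."""
        p = SimParams(beta_mat=0.0, beta_soc=0.0, focal_family_boost=0.0, seed=6, **SMALL)
        study = simulate_study(p)
        mo, un = _mo_and_unrelated_sims(study)
        assert len(mo) >= 5
        obs = mo.mean() - un.mean()
        rng = np.random.default_rng(0)
        pooled = np.concatenate([mo, un])
        count = 0
        for _ in range(999):
            rng.shuffle(pooled)
            diff = pooled[: len(mo)].mean() - pooled[len(mo):].mean()
            if abs(diff) >= abs(obs):
                count += 1
        assert (1 + count) / 1000 > 0.01

    def test_maternal_excess_wanes_for_adult_offspring(self):
        """beta_mat > 0 with adult_decay = 0: immature offspring share extra
        ASVs with their mother; adult offspring do not (Monte-Carlo mean)."""
        imm_excess, adult_excess = [], []
        for seed in range(20):
            p = SimParams(beta_mat=2.0, beta_soc=0.0, adult_decay=0.0, seed=seed, **SMALL)
            study = simulate_study(p)
            meta = study.metadata
            ped = study.pedigree
            presence = study.asv.data > 0
            ind_of = dict(zip(meta["sample_id"], meta["individual_id"]))
            age_of = dict(zip(meta["sample_id"], meta["age_class"]))
            mother_of = dict(zip(study.population.individuals["individual_id"],
                                 study.population.individuals["mother_id"]))
            adult_ids = set(meta.loc[meta["age_class"] == "adult", "sample_id"])
            for stratum, store in (("immature", imm_excess), ("adult", adult_excess)):
                mo_vals, un_vals = [], []
                for sa in meta.loc[meta["age_class"] == stratum, "sample_id"]:
                    off = ind_of[sa]
                    if pd.isna(mother_of.get(off)):
                        continue
                    for sb in adult_ids:
                        other = ind_of[sb]
                        if other == off:
                            continue
                        j = jaccard_similarity(presence.loc[sa], presence.loc[sb])
                        if mother_of[off] == other:
                            mo_vals.append(j)
                        else:
                            un_vals.append(j)
                if mo_vals:
                    store.append(np.mean(mo_vals) - np.mean(un_vals))
        assert np.mean(imm_excess) > 0.02
        assert abs(np.mean(adult_excess)) < np.mean(imm_excess) / 3

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_focal_family_dominates_joint_presence(self, seed):
        """With a strong focal boost, the focal family accounts for the most
        jointly-present ASVs among mother-offspring dyads relative to its
        richness. Uses a clean maternal-only scenario (social route off,
        offspring sampled young) where the attribution is unambiguous."""
        p = SimParams(
            n_individuals=24, n_mothers=5, litter_size_mean=2.0, n_families=6,
            asvs_per_family_mean=8.0, samples_per_individual=2.0, n_nights=90,
            focal_prevalence_boost=0.5, beta_mat=0.3, focal_family_boost=19.0,
            beta_soc=0.0, adult_decay=1.0, dirichlet_alpha=1.0,
            carriage_persistence=0.95, read_depth=8000,
            maturation_nights=90, resident_fraction=1.0, seed=seed,
        )
        study = simulate_study(p)
        meta = study.metadata
        ped = study.pedigree
        fam = study.taxonomy.family_of()
        presence = study.asv.data > 0
        ind_of = dict(zip(meta["sample_id"], meta["individual_id"]))
        joint = np.zeros(study.asv.data.shape[1])
        n_mo = 0
        for sa, sb in itertools.combinations(meta["sample_id"], 2):
            if ind_of[sa] == ind_of[sb]:
                continue
            if mother_offspring(ped, ind_of[sa], ind_of[sb]):
                joint += (presence.loc[sa] & presence.loc[sb]).to_numpy()
                n_mo += 1
        assert n_mo > 0
        share = pd.Series(joint, index=study.asv.data.columns).groupby(fam).sum()
        richness = fam.value_counts()
        per_asv = (share / richness).dropna()
        assert per_asv.idxmax() == study.population.effects.focal_family

    def test_missing_individual_in_sri_named(self):
        p = SimParams(seed=10, **SMALL)
        pop = simulate_population(p)
        logs = simulate_logger_records(pop, p)
        inds = list(pop.individuals["individual_id"])
        sri = sri_matrix(logs, individuals=inds[:-1])
        with pytest.raises(KeyError, match=inds[-1]):
            simulate_microbiota(pop, sri, p)

    def test_beta_soc_raises_top_sri_dyad_similarity(self):
        """Planted social transmission separates strongly-associated dyads
        from never-associated ones, increasingly so with beta_soc."""
        gaps = {0.0: [], 1.5: [], 3.0: []}
        for beta_soc in gaps:
            for seed in range(6):
                p = SimParams(beta_soc=beta_soc, beta_mat=0.0, seed=seed, **SMALL)
                study = simulate_study(p)
                meta = study.metadata
                ind_of = dict(zip(meta["sample_id"], meta["individual_id"]))
                presence = study.asv.data > 0
                sri = study.sri.data
                top, zero = [], []
                vals = sri.to_numpy()[np.triu_indices(len(sri), k=1)]
                thresh = np.quantile(vals[vals > 0], 0.75) if (vals > 0).any() else 0
                for sa, sb in itertools.combinations(meta["sample_id"], 2):
                    ia, ib = ind_of[sa], ind_of[sb]
                    if ia == ib:
                        continue
                    j = jaccard_similarity(presence.loc[sa], presence.loc[sb])
                    s = sri.at[ia, ib]
                    if s == 0:
                        zero.append(j)
                    elif s >= thresh:
                        top.append(j)
                gaps[beta_soc].append(np.mean(top) - np.mean(zero))
        means = {k: np.mean(v) for k, v in gaps.items()}
        assert means[0.0] < means[1.5] < means[3.0]


class TestFixtureOutput:
    def test_writes_standard_inputs_and_truth(self, tmp_path):
        study = simulate_study(SimParams(seed=12, **SMALL))
        write_study(study, tmp_path)
        for name in ("asv.tsv", "taxonomy.tsv", "metadata.csv", "pedigree.csv",
                     "loggers.csv", "truth.json"):
            assert (tmp_path / name).exists()
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["effects"]["beta_mat"] == study.params.beta_mat
        assert truth["effects"]["focal_family"] == study.population.effects.focal_family
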