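"""Synthetic study generator with planted transmission effects.

Emulates a longitudinal wild-rodent microbiota study — a trappable
population with a known mother-offspring pedigree, nightly PIT-tag logger
detections on a grid of stations, repeated faecal samples per individual in
two age classes (immature/adult), and an ASV table organised into bacterial
families — so that every downstream stage of the dyadic pipeline can be
verified by parameter recovery against a known ground truth.

Generative model for a sample of individual i at age class a: ASV j of
family f is present with probability

    logistic(alpha_j + B_mat(a, f) * M_ij + beta_soc * S_ij)

where alpha_j ~ Normal(baseline_logit_mean, baseline_logit_sd) is the ASV's
baseline prevalence (shifted per host by delta_i ~ Normal(0,
individual_logit_sd) and per sample by eps_s ~ Normal(0, sample_logit_sd),
emulating host filtering and sample-to-sample condition differences — these
are what the model's multi-membership random intercepts absorb), M_ij = 1 iff i's mother carries j in her latent
repertoire (her union of present ASVs over her own samples, fixed before
offspring sampling), and S_ij is the SRI-weighted carriage prevalence of j
among i's social contacts (0 when i has no contacts).

Within-host persistence is generated with a copula trick: each
(individual, ASV) pair draws one persistent carriage propensity
U_ij ~ Uniform(0,1), and a sample shows ASV j present iff U_ij (refreshed
with probability 1 - carriage_persistence per sample) falls below that
sample's logistic presence probability. Marginally every sample obeys the
logistic model above, but an individual's samples are strongly correlated
— hosts carry a stable community, contacts are exposed to the taxa a host
persistently carries (its carriage state, the same state its own samples
display), and when adult_decay < 1 the maternally-boosted taxa whose
propensity no longer clears the lowered adult threshold drop out as
offspring age. Social exposure is computed from these time-invariant
carriage states, so the planted social signal is age-homogeneous by
construction. The maternal
boost is

    B_mat(a, f) = beta_mat * (1 if a == immature else adult_decay)
                  * (1 + focal_family_boost * 1[f == focal family])

so adult_decay = 0 switches maternal transmission off in adulthood, and one
designated family (a *Muribaculaceae* analogue, planted at median richness)
carries a disproportionate share of the maternal signal. The focal family
also gets a mild baseline-prevalence bump (focal_prevalence_boost, logit
scale) so that mothers reliably carry some of it; keeping the bump small
matters, because a universally prevalent family is shared by everyone and
its transmission signal stops being mother-offspring-specific. Abundances of
present ASVs are symmetric-Dirichlet weights (concentration
dirichlet_alpha < 1 gives the skewed, few-taxa-dominated profiles typical
of gut communities) scaled to a fixed read depth by multinomial sampling,
so rare present ASVs can drop below the detection limit — the integer
table carries realistic presence noise and is a genuine substrate for the
singleton filter.

None of these distributional choices is estimated from field data; they are
artifact-level conventions, documented as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable
from .socialnet import SriMatrix, sri_matrix
from .taxa import AsvTable, TaxonomyTable


@dataclass
class SimParams:
    """Knobs of the synthetic study; defaults emulate the target field study
    (~70 individuals, 6 mothers, ~3 samples each over ~14 months, nine
    loggers on a ~150 m arena)."""

    n_individuals: int = 70
    n_mothers: int = 6
    litter_size_mean: float = 3.0
    n_families: int = 30
    asvs_per_family_mean: float = 8.0
    baseline_logit_mean: float = -2.0
    baseline_logit_sd: float = 1.0
    beta_mat: float = 1.5
    focal_family_boost: float = 1.0
    focal_prevalence_boost: float = 0.5
    beta_soc: float = 1.5
    adult_decay: float = 0.25
    individual_logit_sd: float = 0.5
    sample_logit_sd: float = 0.25
    maturation_nights: int = 60
    n_nights: int = 180
    n_loggers: int = 9
    arena_size: float = 150.0
    detection_rate: float = 0.3
    resident_fraction: float = 0.5
    samples_per_individual: float = 3.0
    read_depth: int = 2000
    carriage_persistence: float = 0.9
    dirichlet_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_mothers", "n_families", "n_nights", "n_loggers"):
            if getattr(self, name) < (0 if name == "n_mothers" else 1):
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.adult_decay <= 1.0:
            raise ValueError("adult_decay must lie in [0, 1]")
        if not 0.0 < self.detection_rate <= 1.0:
            raise ValueError("detection_rate must lie in (0, 1]")
        if self.samples_per_individual < 1:
            raise ValueError("samples_per_individual must be >= 1")
        if not 0.0 <= self.carriage_persistence <= 1.0:
            raise ValueError("carriage_persistence must lie in [0, 1]")
        if not 0.0 <= self.resident_fraction <= 1.0:
            raise ValueError("resident_fraction must lie in [0, 1]")
        expected = self.n_mothers * (1.0 + self.litter_size_mean)
        if expected > self.n_individuals:
            raise ValueError(
                f"n_mothers={self.n_mothers} with litter_size_mean="
                f"{self.litter_size_mean} implies ~{expected:.0f} individuals "
                f"> n_individuals={self.n_individuals}"
            )


@dataclass
class TruthEffects:
    """The planted transmission parameters downstream fits should recover."""

    beta_mat: float
    beta_soc: float
    adult_decay: float
    focal_family: str
    focal_family_boost: float


@dataclass
class PopulationTruth:
    """Simulated population: individuals, sampling occasions, planted truth."""

    individuals: pd.DataFrame  # individual_id, sex, mother_id, father_id, home_x, home_y, entry_night
    samples: pd.DataFrame      # sample_id, individual_id, day, date, age_class, sex
    effects: TruthEffects
    params: SimParams

    def pedigree(self) -> PedigreeTable:
        ped = self.individuals.set_index("individual_id")[["mother_id", "father_id", "sex"]]
        return PedigreeTable(ped)

    def metadata(self) -> pd.DataFrame:
        out = self.samples[["sample_id", "individual_id", "date", "age_class", "sex"]].copy()
        return out


STUDY_START = pd.Timestamp("2014-11-01")


def focal_family_name(params: SimParams) -> str:
    """The designated high-maternal-transmission family (fixed middle index)."""
    return f"Family_f{(params.n_families + 1) // 2:02d}"


def simulate_population(params: SimParams) -> PopulationTruth:
    """Draw the population, pedigree and sampling occasions.

    n_mothers founder females each produce a litter of 1 + Poisson(mean - 1)
    offspring; each litter shares one father drawn from the founder males
    (half-siblings arise when litters share a father). Offspring home
    centres disperse a short distance from the mother's; offspring enter the
    study mid-way and are immature (juvenile/subadult) for their first
    maturation_nights nights, adult afterwards, so early samples of an
    offspring are immature and later ones adult.
    """
    rng = np.random.default_rng([params.seed, 0])
    mothers = [f"M{i + 1:02d}" for i in range(params.n_mothers)]
    litters = 1 + rng.poisson(max(params.litter_size_mean - 1.0, 0.0), size=params.n_mothers) \
        if params.n_mothers else np.array([], dtype=int)
    n_off = int(litters.sum())
    if params.n_mothers + n_off > params.n_individuals:
        raise ValueError(
            f"drawn litters ({n_off} offspring) plus {params.n_mothers} mothers "
            f"exceed n_individuals={params.n_individuals}"
        )
    n_founders = params.n_individuals - params.n_mothers - n_off
    founders = [f"F{i + 1:02d}" for i in range(n_founders)]
    founder_sex = rng.choice(["F", "M"], size=n_founders)
    males = [f for f, s in zip(founders, founder_sex) if s == "M"]

    rows = []
    for m in mothers:
        rows.append((m, "F", None, None))
    for f, s in zip(founders, founder_sex):
        rows.append((f, s, None, None))
    k = 0
    for m, size in zip(mothers, litters):
        father = rng.choice(males) if males else None
        for _ in range(size):
            k += 1
            rows.append((f"O{k:02d}", rng.choice(["F", "M"]), m, father))
    ind = pd.DataFrame(rows, columns=["individual_id", "sex", "mother_id", "father_id"])

    home = rng.uniform(0, params.arena_size, size=(len(ind), 2))
    mother_home = {m: home[i] for i, m in enumerate(ind["individual_id"]) if m in mothers}
    is_off = ind["mother_id"].notna().to_numpy()
    for i in np.flatnonzero(is_off):
        center = mother_home[ind.at[i, "mother_id"]]
        home[i] = np.clip(
            center + rng.normal(0, params.arena_size / 10.0, size=2), 0, params.arena_size
        )
    ind["home_x"], ind["home_y"] = home[:, 0], home[:, 1]
    entry = np.ones(len(ind), dtype=int)
    entry[is_off] = rng.integers(
        int(0.3 * params.n_nights), int(0.7 * params.n_nights) + 1, size=is_off.sum()
    )
    # non-mother founders: a resident_fraction are adults present from night
    # 1; the rest are young-of-year that enter during the study and mature
    is_founder = (~is_off) & (~ind["individual_id"].isin(mothers)).to_numpy()
    young = is_founder & (rng.uniform(size=len(ind)) > params.resident_fraction)
    entry[young] = rng.integers(1, int(0.7 * params.n_nights) + 1, size=young.sum())
    ind["entry_night"] = entry
    ind["matures"] = is_off | young

    srows = []
    sid = 0
    for i, r in ind.iterrows():
        n_i = 1 + rng.poisson(max(params.samples_per_individual - 1.0, 0.0))
        n_i = min(n_i, params.n_nights - r["entry_night"] + 1)
        lo, hi = int(r["entry_night"]), params.n_nights
        mat_day = lo + params.maturation_nights
        if r["matures"]:
            # longitudinal design straddles maturation: one sample while
            # immature, one as adult when possible, the rest anywhere
            days = [int(rng.integers(lo, min(mat_day, hi + 1)))]
            if n_i >= 2 and mat_day <= hi:
                days.append(int(rng.integers(mat_day, hi + 1)))
            pool = np.setdiff1d(np.arange(lo, hi + 1), days)
            extra = min(n_i - len(days), pool.size)
            if extra > 0:
                days.extend(rng.choice(pool, size=extra, replace=False))
            days = np.sort(np.array(days))
        else:
            days = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_i, replace=False))
        for j, day in enumerate(days):
            sid += 1
            age = (
                "immature"
                if r["matures"] and day < r["entry_night"] + params.maturation_nights
                else "adult"
            )
            srows.append((f"S{sid:04d}", r["individual_id"], int(day),
                          STUDY_START + pd.Timedelta(days=int(day)), age, r["sex"]))
    samples = pd.DataFrame(
        srows, columns=["sample_id", "individual_id", "day", "date", "age_class", "sex"]
    )
    effects = TruthEffects(
        beta_mat=params.beta_mat,
        beta_soc=params.beta_soc,
        adult_decay=params.adult_decay,
        focal_family=focal_family_name(params),
        focal_family_boost=params.focal_family_boost,
    )
    return PopulationTruth(individuals=ind, samples=samples, effects=effects, params=params)


def simulate_logger_records(pop: PopulationTruth, params: SimParams) -> pd.DataFrame:
    """Nightly detections at a regular grid of logger stations.

    Each night within an individual's active window it is detected with
    probability detection_rate, at a station chosen with weight
    exp(-d^2 / (2 rho^2)) in its distance d from the home centre
    (rho = arena_size / 12, a tight kernel emulating territorial space use:
    each individual concentrates on one or two stations, so the association
    network is sparse with a few strong edges), so detections cluster near
    home and co-detection falls off with home-centre distance. Individuals that would end up with
    no detections get one forced detection at their nearest station so the
    SRI matrix covers the whole population.
    """
    rng = np.random.default_rng([params.seed, 1])
    g = int(np.ceil(np.sqrt(params.n_loggers)))
    xs = (np.arange(g) + 1) * params.arena_size / (g + 1)
    grid = np.array([(x, y) for x in xs for y in xs])[: params.n_loggers]
    loc_ids = [f"L{i + 1:02d}" for i in range(params.n_loggers)]
    rho = params.arena_size / 12.0

    rows = []
    for _, r in pop.individuals.iterrows():
        d2 = ((grid - np.array([r["home_x"], r["home_y"]])) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2 * rho * rho))
        w = w / w.sum()
        nights = np.arange(int(r["entry_night"]), params.n_nights + 1)
        detected = rng.uniform(size=nights.size) < params.detection_rate
        hit_nights = nights[detected]
        locs = rng.choice(params.n_loggers, size=hit_nights.size, p=w)
        if hit_nights.size == 0:
            hit_nights = np.array([int(rng.choice(nights))])
            locs = np.array([int(np.argmin(d2))])
        for night, li in zip(hit_nights, locs):
            rows.append((r["individual_id"], loc_ids[li], grid[li, 0], grid[li, 1], int(night)))
    return pd.DataFrame(rows, columns=["individual_id", "location_id", "x", "y", "night"])


def _family_richness(params: SimParams, rng: np.random.Generator) -> dict[str, int]:
    names = [f"Family_f{i + 1:02d}" for i in range(params.n_families)]
    sizes = 1 + rng.poisson(max(params.asvs_per_family_mean - 1.0, 0.0), size=params.n_families)
    # plant the focal family at median richness so attribution is separable
    # from richness by construction
    focal = focal_family_name(params)
    fi = names.index(focal)
    order = np.argsort(sizes)
    mi = int(order[len(order) // 2])
    sizes[fi], sizes[mi] = sizes[mi], sizes[fi]
    return dict(zip(names, (int(s) for s in sizes)))


def simulate_microbiota(
    pop: PopulationTruth, sri: SriMatrix, params: SimParams
) -> tuple[AsvTable, TaxonomyTable]:
    """Generate the ASV count table and taxonomy under the planted effects."""
    missing = [
        i for i in pop.individuals["individual_id"] if i not in sri.data.index
    ]
    if missing:
        raise KeyError(f"individuals missing from SRI matrix: {missing}")
    rng = np.random.default_rng([params.seed, 2])

    richness = _family_richness(params, rng)
    fam_of_asv: list[str] = []
    asv_ids: list[str] = []
    for fam, size in richness.items():
        for _ in range(size):
            asv_ids.append(f"ASV{len(asv_ids) + 1:04d}")
            fam_of_asv.append(fam)
    n_asv = len(asv_ids)
    fam_arr = np.array(fam_of_asv)
    focal = pop.effects.focal_family
    alpha = rng.normal(params.baseline_logit_mean, params.baseline_logit_sd, size=n_asv)
    # the focal family emulates a dominant, highly prevalent gut family, so
    # mothers actually carry it and can pass it on
    alpha = alpha + params.focal_prevalence_boost * (fam_arr == focal)

    tax = pd.DataFrame(
        {
            "kingdom": "k__Bacteria",
            "phylum": "p__SimPhylum",
            "class": "c__SimClass",
            "order": "o__SimOrder",
            "family": [f"f__{f}" for f in fam_arr],
            "genus": pd.NA,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )

    inds = list(pop.individuals["individual_id"])
    ind_ix = {v: i for i, v in enumerate(inds)}
    mother_of = dict(
        zip(pop.individuals["individual_id"], pop.individuals["mother_id"])
    )
    sri_mat = sri.data.loc[inds, inds].to_numpy()
    np.fill_diagonal(sri_mat, 0.0)

    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    n_ind = len(inds)
    delta_ind = rng.normal(0.0, params.individual_logit_sd, size=n_ind)
    # persistent carriage propensity: one uniform per (individual, ASV); all
    # of an individual's samples threshold the same propensity, so carriage
    # persists within hosts while each sample's marginal presence
    # probability is exactly the logistic model
    U = rng.uniform(size=(n_ind, n_asv))
    boost_imm = params.beta_mat * (1.0 + params.focal_family_boost * (fam_arr == focal))

    mother_ids = set(pd.unique(pop.individuals["mother_id"].dropna()))
    is_off = {r["individual_id"]: pd.notna(r["mother_id"])
              for _, r in pop.individuals.iterrows()}

    # carriage states, built in dependency order:
    # baseline -> founders/mothers (social only) -> mothers' samples (their
    # union = the maternal repertoire) -> offspring (maternal + social)
    c0 = U < _sigmoid(alpha[None, :] + delta_ind[:, None])
    carriage = c0.copy()

    def _social_exposure(i: int, state: np.ndarray) -> np.ndarray:
        w = sri_mat[i]
        wsum = w.sum()
        return (w @ state) / wsum if wsum > 0 else np.zeros(n_asv)

    for i, ind in enumerate(inds):
        if not is_off[ind]:
            s_vec = _social_exposure(i, c0)
            carriage[i] = U[i] < _sigmoid(alpha + delta_ind[i] + params.beta_soc * s_vec)

    counts = np.zeros((len(pop.samples), n_asv), dtype=int)
    sample_pos = {s: i for i, s in enumerate(pop.samples["sample_id"])}
    maternal_rep: dict[str, np.ndarray] = {}

    def _draw_sample(row, m_vec: np.ndarray, s_vec: np.ndarray) -> np.ndarray:
        i = ind_ix[row["individual_id"]]
        decay = 1.0 if row["age_class"] == "immature" else params.adult_decay
        b_mat = params.beta_mat * decay * (
            1.0 + params.focal_family_boost * (fam_arr == focal)
        )
        eps = rng.normal(0.0, params.sample_logit_sd)
        p = _sigmoid(alpha + delta_ind[i] + eps + b_mat * m_vec
                     + params.beta_soc * s_vec)
        refresh = rng.uniform(size=n_asv) >= params.carriage_persistence
        v = np.where(refresh, rng.uniform(size=n_asv), U[i])
        present = v < p
        if not present.any():
            present[int(np.argmax(p))] = True
        k = int(present.sum())
        weights = rng.dirichlet(np.full(k, params.dirichlet_alpha))
        out = np.zeros(n_asv, dtype=int)
        out[present] = rng.multinomial(params.read_depth, weights)
        return out

    zeros = np.zeros(n_asv)
    samp = pop.samples.sort_values("day", kind="stable")
    for _, row in samp[samp["individual_id"].isin(mother_ids)].iterrows():
        i = ind_ix[row["individual_id"]]
        c = _draw_sample(row, zeros, _social_exposure(i, carriage))
        counts[sample_pos[row["sample_id"]]] = c
        prev = maternal_rep.get(row["individual_id"], np.zeros(n_asv, dtype=bool))
        maternal_rep[row["individual_id"]] = prev | (c > 0)

    # offspring carriage: maternal repertoire (mother's union of realised
    # samples, fixed before any offspring sampling) plus social exposure
    for i, ind in enumerate(inds):
        if is_off[ind]:
            mom = mother_of[ind]
            m_vec = maternal_rep.get(mom, carriage[ind_ix[mom]]).astype(float)
            s_vec = _social_exposure(i, carriage)
            carriage[i] = U[i] < _sigmoid(
                alpha + delta_ind[i] + boost_imm * m_vec + params.beta_soc * s_vec
            )

    for _, row in samp[~samp["individual_id"].isin(mother_ids)].iterrows():
        ind = row["individual_id"]
        i = ind_ix[ind]
        if is_off[ind]:
            mom = mother_of[ind]
            m_vec = maternal_rep.get(mom, carriage[ind_ix[mom]]).astype(float)
        else:
            m_vec = zeros
        counts[sample_pos[row["sample_id"]]] = _draw_sample(
            row, m_vec, _social_exposure(i, carriage)
        )

    table = AsvTable(
        pd.DataFrame(counts, index=pop.samples["sample_id"].to_numpy(), columns=asv_ids,
                     dtype=float),
        mode="counts",
    )
    return table, TaxonomyTable(tax)


@dataclass
class SyntheticStudy:
    """Everything one simulated study produces, plus the planted truth."""

    params: SimParams
    population: PopulationTruth
    loggers: pd.DataFrame
    sri: SriMatrix
    asv: AsvTable
    taxonomy: TaxonomyTable

    @property
    def metadata(self) -> pd.DataFrame:
        return self.population.metadata()

    @property
    def pedigree(self) -> PedigreeTable:
        return self.population.pedigree()


def simulate_study(params: SimParams) -> SyntheticStudy:
    """Population -> logger records -> SRI -> microbiota, in one call."""
    pop = simulate_population(params)
    logs = simulate_logger_records(pop, params)
    sri = sri_matrix(logs, individuals=list(pop.individuals["individual_id"]))
    asv, tax = simulate_microbiota(pop, sri, params)
    return SyntheticStudy(
        params=params, population=pop, loggers=logs, sri=sri, asv=asv, taxonomy=tax
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the five standard pipeline inputs plus the truth JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    study.asv.data.to_csv(os.path.join(outdir, "asv.tsv"), sep="\t", index_label="sample_id")
    study.taxonomy.data.to_csv(os.path.join(outdir, "taxonomy.tsv"), sep="\t",
                               index_label="asv_id")
    study.metadata.to_csv(os.path.join(outdir, "metadata.csv"), index=False)
    study.pedigree.data.to_csv(os.path.join(outdir, "pedigree.csv"),
                               index_label="individual_id")
    study.loggers.to_csv(os.path.join(outdir, "loggers.csv"), index=False)
    truth = {"params": asdict(study.params), "effects": asdict(study.population.effects)}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
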