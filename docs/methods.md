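# Methods

This note documents the statistical model, the synthetic-study generator,
and the numerical choices made throughout `microdyad`, at the level of
detail a user needs to judge what a passing test suite does and does not
demonstrate.

## The dyadic Beta model

**Likelihood.** For dyad *d* — an unordered pair of samples from two
different individuals — the similarity response must lie strictly in (0,1)
and is modelled as

    y_d ~ Beta(mu_d * phi, (1 - mu_d) * phi)
    logit(mu_d) = b0 + x_d' b + u_A(d) + u_B(d) + w_sA(d) + w_sB(d)

where `phi > 0` is the Beta precision (Var(y|mu) = mu(1-mu)/(1+phi)). The
two multi-membership terms give each dyad the *sum* of its two individuals'
random intercepts `u_i ~ Normal(0, sigma_ind)` and its two samples'
intercepts `w_s ~ Normal(0, sigma_samp)`, with equal weight per member.
They absorb "this individual/sample is globally more or less similar to
everything" variation; they cannot absorb pair-specific dependence (see
*Limitations*).

**Covariates.** mo_status (1 iff one member is the recorded mother of the
other; father-offspring pairs are 0), relatedness (0 / 0.25 / 0.5),
adjusted SRI, age-class similarity (same class = 1), sex similarity,
spatial distance between logger centroids (m), sampling interval (days).
Continuous covariates (sri, relatedness, spatial_dist, interval_days) are
centred and scaled to unit SD by default so effect sizes are comparable
across predictors; binary covariates stay 0/1. Zero-variance columns are
left unscaled with a warning. Interactions available as products of main
effects; the scientific model adds mo_status x age_sim and sri x age_sim.

**Response transform.** Observed similarities can hit 0 or 1, outside the
Beta support. The pipeline applies the Smithson–Verkuilen compression
`y' = (y (n-1) + 0.5) / n` once, after the exclusion filters, with `n` the
final dyad count.

**Priors** (configurable via `model.Priors`): Normal(0, 2.5) on all
coefficients (intended for standardized predictors), half-Student-t(3, 0,
2.5) on both random-effect SDs, Gamma(0.01, 0.01) on `phi`. These are
weakly-informative defaults in the style of contemporary Bayesian
regression software.

**Sampler.** Hamiltonian Monte Carlo with hand-derived analytic gradients
on the unconstrained space: coefficients and random effects sampled
directly (the *centred* parameterization — every individual and sample
appears in many dyads, so the groups are data-rich and centring mixes far
better than the non-centred form here), `log sigma_ind`, `log sigma_samp`,
`log phi` log-transformed with Jacobians. Step size adapts by dual
averaging toward 0.8 acceptance; a diagonal mass matrix is estimated once
from the 25–75% warmup window (Stan-style shrinkage toward a small
regulariser); trajectory length 0.8 with the leapfrog count jittered ±25%
and capped at 32 steps; divergent or non-finite trajectories are rejected.
Defaults: 4 chains x (1,000 warmup + 1,000 draws); a reduced preset (2 x
(500+500)) exists for the attribution scan, and the test suite runs the scan at 2 x
(300+300) with shortened trajectories, where MCMC error on the per-family
deltas is an order of magnitude below the planted attenuation. All randomness flows through seeded numpy
Generators; identical settings give bit-identical draws. The gradient
kernel is numba-compiled; a pure-numpy reference implementation of the same
log posterior is kept and the two are cross-checked to float tolerance in
the tests (plus a finite-difference check of the gradients during
development). Degenerate inputs: responses outside (0,1) raise with an
instruction to squeeze; acceptance collapse raises with the settings
echoed; `sigma` or `phi` underflow returns log-density -inf rather than
propagating NaNs.

**Diagnostics.** `check_convergence` computes split-Rhat (rank-normalised,
via arviz) for all fixed effects and hyperparameters, passes iff all are
below the threshold (default 1.05), and optionally writes per-parameter
trace plots. Random-effect levels are treated as nuisance parameters and
not gated. `summarize` reports posterior mean, SD, central 95% interval,
Rhat and a CI-excludes-zero flag (coefficients only — the flag is vacuous
for strictly positive SD/precision parameters).

**Stratum effects.** For a binary modifier, the effect of a term at
modifier level m is `beta_main + m * beta_interaction`, evaluated draw-wise
so the interval is a true posterior interval. Because the exclusion filters
guarantee that mixed-age mother-offspring pairs always have the offspring
as the immature member, level 0 reads as the adult-immature (young
offspring) maternal effect and level 1 as the adult-adult effect.

## Dyad construction and exclusion filters

One row per unordered between-individual sample pair; within-individual
pairs are excluded. Two filters follow: (i) drop pairs where both samples
are immature; (ii) drop mother-offspring pairs where the *mother's* sample
is immature. The removal sets can overlap (a mother sampled as immature
paired with an immature offspring); `FilterReport` therefore always records
both set sizes, their intersection, and the final counts, and refuses
internally inconsistent bookkeeping. Dates are day-resolution; the sampling
interval is the absolute difference in whole days.

## ASV-table processing

Fixed, logged filter order: non-gut lineage removal (default Cyanobacteria
and Mitochondria, matched case-insensitively at any rank after stripping
`k__`-style prefixes) → singleton removal (default: total count across the
dataset ≤ 1; a present-in-exactly-one-sample variant is available behind a
flag) → proportional normalisation per sample. Jaccard similarity
(|shared| / |union| on presence = abundance > 0) is invariant to the
normalisation step; Bray-Curtis similarity (1 − Σ|a−b| / Σ(a+b)) requires
proportions. Presence has no minimum-abundance cut. Family exclusion for
the attribution scan matches the family rank exactly after prefix
stripping; ASVs with unassigned family are never excluded and are reported
as an "Unassigned" pseudo-family (not scanned). Similarity of two empty
samples is undefined and raises; tables are read from TSV (either
orientation) or BIOM 2.1 HDF5.

## Adjusted SRI and space use

Two individuals are associated on a night (one 12-h window) if detected at
the same station that night; duplicates within a night count once. The
adjusted SRI restricts the tally to the nights inside both individuals'
observation lifespans (first to last detection): x co-detected nights over
d nights where at least one was detected, 0 if the joint window is empty.
This implements the published one-sentence summary of the index literally;
whether the original index also corrects for logger absence from an
individual's range is not determinable from that summary and is
deliberately not guessed. Note one subtlety: *recomputing* the index after
truncating the records to the joint window is not guaranteed to be
idempotent, because truncation can shrink an individual's inferred
lifespan; the invariants that do hold (third-party records and
neither-detected nights are irrelevant) are the ones tested. Spatial
centroids are unweighted means of detection coordinates; distances are
Euclidean.

## Pedigree coding

Parent-offspring and full siblings 0.5, half siblings (exactly one shared
recorded parent) 0.25, otherwise 0; missing parents are distinct unknowns.
mother_offspring is 1 only for mother-offspring pairs. Only first-degree
and half-sibling links are coded; grandparents and deeper kin map to 0.

## Mantel test

Pearson correlation of lower-triangle entries; the null distribution
permutes the second matrix's row/column labels jointly. Two-sided, add-one
convention, default 9,999 permutations; an exact variant enumerates all n!
permutations for n ≤ 8 and is used as the oracle in tests.

## The synthetic-study generator

The generator is first-class code: it emulates a longitudinal wild-rodent
study well enough that the pipeline's inferences can be checked by
parameter recovery, while remaining an artifact — none of its
distributional choices is estimated from field data.

**Population.** `n_mothers` founder females each produce `1 +
Poisson(litter_size_mean - 1)` offspring (a parameter error if the expected
population exceeds `n_individuals`); each litter shares a father drawn from
the founder males, so half-siblings arise when litters share one. Offspring
home centres disperse a short normal jump from the mother's; offspring
enter the study mid-way; a configurable fraction of the other founders are
residents (adult from night 1), the rest young-of-year that enter during
the study. Every entering-young individual is immature for its first
`maturation_nights` nights (default 60) and adult after, and its sampling
occasions straddle maturation when its window allows — matching the
longitudinal design in which young animals are followed into adulthood and
yielding roughly a one-third immature sample fraction at the default
settings.

**Loggers.** Stations on a regular grid; per night in its active window an
individual is detected with probability `detection_rate` at a station
weighted by `exp(-d^2 / (2 rho^2))` from its home centre with `rho =
arena_size / 12` — a tight kernel that produces the sparse,
few-strong-edges association networks of territorial mice. An individual
that would end with zero detections gets one forced detection so the SRI
matrix covers the population.

**Microbiota.** ASV j (family f, baseline logit `alpha_j ~
Normal(baseline_logit_mean, baseline_logit_sd)`) is present in a sample of
individual i at age class a with probability

    logistic(alpha_j + delta_i + eps_s + B_mat(a, f) * M_ij + beta_soc * S_ij)

with host effects `delta_i ~ Normal(0, individual_logit_sd)` and sample
effects `eps_s ~ Normal(0, sample_logit_sd)` (what the model's
multi-membership intercepts absorb), `M_ij = 1` iff i's mother carries j in
her maternal repertoire — the union of present ASVs over her own samples,
fixed before any offspring are sampled — and `S_ij` the SRI-weighted
carriage prevalence of j among i's contacts (0 without contacts). The
maternal boost is

    B_mat(a, f) = beta_mat * (1 if a = immature else adult_decay)
                  * (1 + focal_family_boost * 1[f = focal family])

so `adult_decay = 0` switches maternal transmission off in adulthood and
one designated family (planted at median richness, optionally with a
`focal_prevalence_boost` logit bump) carries a disproportionate share of
the maternal signal.

**Within-host persistence (the carriage copula).** Each (individual, ASV)
pair draws one persistent uniform `U_ij`; a sample shows the ASV present
iff `U_ij` — refreshed with probability `1 - carriage_persistence` per
sample — falls below that sample's presence probability. Marginally every
sample obeys the logistic model above, but an individual's samples are
strongly correlated: hosts carry a stable community, social contacts are
exposed to the taxa a host persistently carries (the same carriage its own
samples display), and under `adult_decay < 1` the maternally-boosted taxa
whose propensity no longer clears the lowered adult threshold drop out as
offspring age. Social exposure is computed from these time-invariant
carriage states, so the planted social signal is age-homogeneous by
construction. An earlier design that exposed individuals to each contact's
*most recent realized sample* was abandoned: it made late-study (adult)
samples track contacts' measured samples more closely than early ones,
planting a spurious social x age interaction, and without any persistence
the social exposure left no trace in the contacts' own measured samples at
all.

**Abundances.** Present ASVs get symmetric Dirichlet weights
(`dirichlet_alpha = 0.5` by default — skewed, few-taxa-dominated profiles)
scaled to `read_depth` reads by multinomial sampling, so rare present taxa
can drop below the detection limit; the integer table carries realistic
presence noise and is a genuine substrate for the singleton filter.

**Defaults** emulate the target study scale: 70 individuals, 6 mothers,
~3 samples each over 180 nights, 9 loggers on a 150 m arena, 30 families
averaging 8 ASVs, baseline prevalence logit −2 (sd 1), `beta_mat = 1.5`,
`beta_soc = 1.5`, `adult_decay = 0.25`, focal prevalence bump +0.5,
carriage persistence 0.9, 60-night maturation, half the founders resident,
read depth 2,000.

## What the verification scenarios show — and what they do not

**Recovery (study scale).** 60 individuals, 6 mothers, ~150 samples,
`beta_mat = 1.5`, `beta_soc = 0.9`, `adult_decay = 0`, reduced sampler.
The fitted interaction model must show: positive mother-offspring effect
(CI excluding 0), significantly negative mo x age interaction, sri x age
interaction covering 0, positive SRI effect — the ontogenetic pattern the
model is designed to detect — in at least 8 of 10 seeds. The social
magnitude 0.9 was chosen by power analysis: strong enough that the SRI
slope is detected with wide margin at ~150 samples, weak enough that the
pair-level dependence the social process creates (see *Limitations*) does
not produce spurious narrow-CI interactions.

**Null calibration.** 20 all-null studies (`beta_mat = beta_soc =
focal_family_boost = 0`); every slope's 95% CI must cover 0 in ≥ 16 of 20
fits. This scenario disables carriage persistence, so the generator matches
the model's conditional-independence structure and the check isolates the
correctness of the likelihood, gradients and sampler. With persistence
active the same fits cover at roughly 70% — a measurement of the model
family's intrinsic limitation with dyadic data (pair-level dependence that
two multi-membership intercepts cannot represent), not of an implementation
error; that number is part of why the recovery scenario's social magnitude
is moderate.

**Attribution.** 40 individuals, 8 mothers, 10 families (~12 ASVs each).
The scan scenario is deliberately clean: offspring remain immature for the
whole study, so every mother-offspring row sits in the main-effect stratum
and sibling pairs — which would otherwise carry the planted maternal
sharing into the relatedness covariate — are removed wholesale by the
immature-immature filter; the social route is off, because social
transmission shares *all* families across spatially-adjacent
mother-offspring pairs in proportion to family richness and so contaminates
per-family attribution; the focal family gets saturated maternal uptake, a
mild (+0.5 logit) prevalence bump, diffuse background maternal
transmission is weak (`beta_mat = 0.3`), and carriage persistence is
moderate (0.85) — at very high persistence each pair's chance carriage
overlap becomes a fixed quantity reused by all its sample pairs, and a
competitor family can show attenuation as large as the planted one by
chance. The planted family must show the
largest attenuation of the mother-offspring main effect in ≥ 9 of 10
scans, and the rank correlation between per-family attenuation and log
richness, averaged over scans, must stay near zero (|mean rho| < 0.35) —
the planted influence is a transmission property, not a richness artifact.

## Known limitations

- **Pair-level dependence.** Dyadic similarity data carries dependence at
  the individual-pair level (two hosts' realized carriage overlap is a
  fixed quantity reused by all their sample pairs). The two multi-membership
  intercepts do not represent it, so credible intervals for pair-level
  covariates are anti-conservative whenever such structure is strong. This
  is a property of the model family itself, visible here only because the
  generator provides ground truth.
- **Attribution is relative.** The leave-one-family-out deltas are bounded
  by the Jaccard mechanics (removing shared taxa also shrinks the union),
  so even a dominant family moves the coefficient modestly; the scan ranks
  families, it does not decompose variance.
- The generator has no environmental reservoir, no seasonality, no
  sequencing-error process, and its social exposure is time-invariant;
  passing tests demonstrate that the pipeline recovers effects generated by
  these mechanisms at these scales, not that field data satisfies them.
- The HMC sampler uses a single diagonal mass adaptation window and a fixed
  trajectory-length cap; severely ill-conditioned posteriors (far outside
  the scales exercised here) would need the full defaults (4 x 1,000+1,000)
  or external tuning.
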