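"""Bayesian dyadic Beta regression with multi-membership random intercepts.

Likelihood, for dyad d with similarity response y_d in (0,1):

    y_d ~ Beta(mu_d * phi, (1 - mu_d) * phi)
    logit(mu_d) = b0 + x_d' b + u_{A(d)} + u_{B(d)} + w_{sA(d)} + w_{sB(d)}

where u are individual-level and w sample-level random intercepts, each
entering once per dyad member (multi-membership, equal weights):

    u_i ~ Normal(0, sigma_ind),  w_s ~ Normal(0, sigma_samp)

Priors (configurable): Normal(0, 2.5) on coefficients (intended for
standardized predictors), half-Student-t(3, 0, 2.5) on both random-effect
SDs, Gamma(0.01, 0.01) on the Beta precision phi.

Sampling is Hamiltonian Monte Carlo on the unconstrained space (random
effects centred — each individual and sample appears in many dyads, so the
groups are data-rich and the centred parameterization mixes well; SDs and
phi log-transformed) with analytic gradients.
Convergence is checked with the split-Rhat statistic; effects are reported
on the logit (linear-predictor) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, digamma

from ._hmc import sample_chain

HYPER_NAMES = ("sigma_individual", "sigma_sample", "phi")


@dataclass
class ModelSpec:
    """Formula of the dyadic model.

    ``interactions`` are pairs of main-effect names; each must be listed in
    ``fixed``. The multi-membership groupings (both individuals, both
    samples) are always included.
    """

    response: str = "jaccard"
    fixed: tuple[str, ...] = (
        "mo_status",
        "sri",
        "relatedness",
        "age_sim",
        "sex_sim",
        "spatial_dist",
        "interval_days",
    )
    interactions: tuple[tuple[str, str], ...] = ()
    #: drop the multi-membership intercepts (misspecification comparisons only)
    random_effects: bool = True

    def __post_init__(self) -> None:
        if self.response not in ("jaccard", "braycurtis"):
            raise ValueError(f"unknown response {self.response!r}")
        for a, b in self.interactions:
            if a not in self.fixed or b not in self.fixed:
                raise ValueError(f"interaction {a}x{b} over terms not in the model")

    @property
    def term_names(self) -> list[str]:
        return ["Intercept", *self.fixed, *(f"{a}:{b}" for a, b in self.interactions)]

    def design_matrix(self, rows: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(rows))]
        for t in self.fixed:
            cols.append(rows[t].to_numpy(dtype=float))
        for a, b in self.interactions:
            cols.append(rows[a].to_numpy(dtype=float) * rows[b].to_numpy(dtype=float))
        return np.column_stack(cols)


@dataclass
class Priors:
    coef_sd: float = 2.5
    sd_scale: float = 2.5   # half-Student-t(3, 0, sd_scale) on sigma's
    sd_df: float = 3.0
    phi_shape: float = 0.01
    phi_rate: float = 0.01


@dataclass
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    traj_len: float = 0.8
    max_leapfrog: int = 32

    @classmethod
    def reduced(cls, seed: int = 0) -> "SamplerSettings":
        """Cheaper preset used for the per-family attribution scan."""
        return cls(chains=2, warmup=500, draws=500, seed=seed)


@dataclass
class PosteriorFit:
    """MCMC draws plus bookkeeping for the fitted dyadic model."""

    spec: ModelSpec
    settings: SamplerSettings
    term_names: list[str]
    individuals: list[str]
    samples: list[str]
    draws: np.ndarray          # (chains, draws, dim) on the unconstrained space
    accept_rates: list[float]
    n_divergent: int

    # layout of the unconstrained parameter vector
    def _slices(self):
        p = len(self.term_names)
        if not self.spec.random_effects:
            return {"beta": slice(0, p), "log_phi": p}
        nu = len(self.individuals)
        nw = len(self.samples)
        return {
            "beta": slice(0, p),
            "u": slice(p, p + nu),
            "w": slice(p + nu, p + nu + nw),
            "log_sigma_ind": p + nu + nw,
            "log_sigma_samp": p + nu + nw + 1,
            "log_phi": p + nu + nw + 2,
        }

    def coef_draws(self, term: str) -> np.ndarray:
        """Draws (chains x draws) for a fixed-effect term, logit scale."""
        if term not in self.term_names:
            raise KeyError(f"term {term!r} not in model: {self.term_names}")
        j = self.term_names.index(term)
        return self.draws[:, :, j]

    def hyper_draws(self, name: str) -> np.ndarray:
        sl = self._slices()
        key = {
            "sigma_individual": "log_sigma_ind",
            "sigma_sample": "log_sigma_samp",
            "phi": "log_phi",
        }[name]
        if key not in sl:
            raise KeyError(f"{name} not in a fit without random effects")
        return np.exp(self.draws[:, :, sl[key]])

    def named_draws(self) -> dict[str, np.ndarray]:
        """Fixed effects + hyperparameters as {name: (chains, draws)}."""
        out = {t: self.coef_draws(t) for t in self.term_names}
        hypers = HYPER_NAMES if self.spec.random_effects else ("phi",)
        for h in hypers:
            out[h] = self.hyper_draws(h)
        return out

    def random_effect_draws(self, group: str) -> np.ndarray:
        """Random-effect draws, (chains, draws, n_levels)."""
        sl = self._slices()
        if group == "individual":
            return self.draws[:, :, sl["u"]]
        if group == "sample":
            return self.draws[:, :, sl["w"]]
        raise KeyError(group)


def _make_logp_grad_fixed(y, X, priors: Priors):
    """Plain Beta regression (no random effects): theta = [beta, log_phi]."""
    n, p = X.shape
    ly = np.log(y)
    l1y = np.log1p(-y)
    logit_y = ly - l1y
    XT = np.ascontiguousarray(X.T)
    a0, b0 = priors.phi_shape, priors.phi_rate
    coef_var = priors.coef_sd ** 2

    def logp_grad(theta):
        beta = theta[:p]
        lphi = theta[-1]
        phi = np.exp(lphi)
        if not np.isfinite(phi) or phi > 1e8:
            return -np.inf, np.zeros_like(theta)
        eta = X @ beta
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        if (a <= 0).any() or (b <= 0).any():
            return -np.inf, np.zeros_like(theta)
        ll = (
            n * gammaln(phi)
            - gammaln(a).sum()
            - gammaln(b).sum()
            + ((a - 1.0) * ly).sum()
            + ((b - 1.0) * l1y).sum()
        )
        dig_a = digamma(a)
        dig_b = digamma(b)
        g_eta = phi * mu * (1.0 - mu) * (dig_b - dig_a + logit_y)
        lp = ll - 0.5 * (beta @ beta) / coef_var + a0 * lphi - b0 * phi
        grad = np.empty_like(theta)
        grad[:p] = XT @ g_eta - beta / coef_var
        dll_dphi = (
            n * digamma(phi)
            - (mu * dig_a).sum()
            - ((1.0 - mu) * dig_b).sum()
            + (mu * ly).sum()
            + ((1.0 - mu) * l1y).sum()
        )
        grad[-1] = phi * dll_dphi + a0 - b0 * phi
        return lp, grad

    return logp_grad


def _make_logp_grad(y, X, ia, ib, sa, sb, nu, nw, priors: Priors):
    """Closure returning (log posterior, gradient) on the unconstrained vector."""
    n, p = X.shape
    ly = np.log(y)
    l1y = np.log1p(-y)
    logit_y = ly - l1y
    XT = np.ascontiguousarray(X.T)
    nu_t, s_t = priors.sd_df, priors.sd_scale
    a0, b0 = priors.phi_shape, priors.phi_rate
    coef_var = priors.coef_sd ** 2

    def logp_grad(theta):
        beta = theta[:p]
        u = theta[p : p + nu]
        w = theta[p + nu : p + nu + nw]
        lsu, lsw, lphi = theta[-3], theta[-2], theta[-1]
        su, sw, phi = np.exp(lsu), np.exp(lsw), np.exp(lphi)
        if not np.isfinite(phi) or phi > 1e8 or phi < 1e-10 or su < 1e-10 or sw < 1e-10:
            return -np.inf, np.zeros_like(theta)

        eta = X @ beta + u[ia] + u[ib] + w[sa] + w[sb]
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        if (a <= 0).any() or (b <= 0).any():
            return -np.inf, np.zeros_like(theta)

        ll = (
            n * gammaln(phi)
            - gammaln(a).sum()
            - gammaln(b).sum()
            + ((a - 1.0) * ly).sum()
            + ((b - 1.0) * l1y).sum()
        )
        dig_a = digamma(a)
        dig_b = digamma(b)
        g_eta = phi * mu * (1.0 - mu) * (dig_b - dig_a + logit_y)

        # priors (centred random effects: u ~ N(0, su), w ~ N(0, sw))
        uu = u @ u
        ww = w @ w
        lp = ll
        lp += -0.5 * (beta @ beta) / coef_var
        lp += -0.5 * uu / (su * su) - nu * lsu
        lp += -0.5 * ww / (sw * sw) - nw * lsw
        for s_val, ls in ((su, lsu), (sw, lsw)):
            lp += -0.5 * (nu_t + 1.0) * np.log1p(s_val * s_val / (nu_t * s_t * s_t)) + ls
        lp += a0 * lphi - b0 * phi

        grad = np.empty_like(theta)
        grad[:p] = XT @ g_eta - beta / coef_var
        gu = np.bincount(ia, weights=g_eta, minlength=nu) + np.bincount(
            ib, weights=g_eta, minlength=nu
        )
        gw = np.bincount(sa, weights=g_eta, minlength=nw) + np.bincount(
            sb, weights=g_eta, minlength=nw
        )
        grad[p : p + nu] = gu - u / (su * su)
        grad[p + nu : p + nu + nw] = gw - w / (sw * sw)

        def dlog_half_t(s_val):
            q = s_val * s_val / (nu_t * s_t * s_t)
            return -(nu_t + 1.0) * q / (1.0 + q) + 1.0

        grad[-3] = uu / (su * su) - nu + dlog_half_t(su)
        grad[-2] = ww / (sw * sw) - nw + dlog_half_t(sw)
        dll_dphi = (
            n * digamma(phi)
            - (mu * dig_a).sum()
            - ((1.0 - mu) * dig_b).sum()
            + (mu * ly).sum()
            + ((1.0 - mu) * l1y).sum()
        )
        grad[-1] = phi * dll_dphi + a0 - b0 * phi
        return lp, grad

    return logp_grad


def fit_beta_mm(
    rows: pd.DataFrame,
    spec: ModelSpec | None = None,
    settings: SamplerSettings | None = None,
    priors: Priors | None = None,
    engine: str = "auto",
) -> PosteriorFit:
    """Fit the dyadic Beta multi-membership model by HMC.

    ``rows`` must carry the response column (strictly inside (0,1); apply
    :func:`microdyad.dyads.squeeze_response` first if needed), the covariate
    columns named in the spec, and individual_a/b, sample_a/b identifiers.

    ``engine`` selects the log-posterior implementation: ``"numba"``
    (compiled, default when available), ``"numpy"`` (reference), or
    ``"auto"``.
    """
    spec = spec or ModelSpec()
    settings = settings or SamplerSettings()
    priors = priors or Priors()

    y = rows[spec.response].to_numpy(dtype=float)
    if (y <= 0).any() or (y >= 1).any():
        raise ValueError(
            "response values must lie strictly in (0,1); "
            "apply dyads.squeeze_response to the similarity column first"
        )
    individuals = sorted(set(rows["individual_a"]) | set(rows["individual_b"]))
    samples = sorted(set(rows["sample_a"]) | set(rows["sample_b"]))
    if len(individuals) < 2:
        raise ValueError("need at least two individuals")
    ind_ix = {v: i for i, v in enumerate(individuals)}
    smp_ix = {v: i for i, v in enumerate(samples)}
    ia = rows["individual_a"].map(ind_ix).to_numpy()
    ib = rows["individual_b"].map(ind_ix).to_numpy()
    sa = rows["sample_a"].map(smp_ix).to_numpy()
    sb = rows["sample_b"].map(smp_ix).to_numpy()
    X = spec.design_matrix(rows)
    nu, nw = len(individuals), len(samples)

    if not spec.random_effects:
        dim = X.shape[1] + 1
        logp_grad = _make_logp_grad_fixed(y, X, priors)
    else:
        dim = X.shape[1] + nu + nw + 3
        if engine == "auto":
            try:
                from ._kernels import make_logp_grad_compiled
                engine = "numba"
            except ImportError:
                engine = "numpy"
        if engine == "numba":
            from ._kernels import make_logp_grad_compiled

            logp_grad = make_logp_grad_compiled(y, X, ia, ib, sa, sb, nu, nw, priors)
        elif engine == "numpy":
            logp_grad = _make_logp_grad(y, X, ia, ib, sa, sb, nu, nw, priors)
        else:
            raise ValueError(f"unknown engine {engine!r}")

    # moment-based starting values, jittered per chain
    ybar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    yvar = float(max(y.var(), 1e-6))
    phi0 = max(ybar * (1 - ybar) / yvar - 1.0, 2.0)

    all_draws = np.empty((settings.chains, settings.draws, dim))
    accept_rates: list[float] = []
    n_div = 0
    for c in range(settings.chains):
        rng = np.random.default_rng([settings.seed, c])
        x0 = np.zeros(dim)
        x0[0] = np.log(ybar / (1 - ybar))
        if spec.random_effects:
            x0[-3] = np.log(0.1)
            x0[-2] = np.log(0.1)
        x0[-1] = np.log(phi0)
        x0 += 0.01 * rng.standard_normal(dim)
        res = sample_chain(
            logp_grad,
            x0,
            n_warmup=settings.warmup,
            n_draws=settings.draws,
            rng=rng,
            target_accept=settings.target_accept,
            traj_len=settings.traj_len,
            max_leapfrog=settings.max_leapfrog,
        )
        all_draws[c] = res.draws
        accept_rates.append(res.accept_rate)
        n_div += res.n_divergent

    if min(accept_rates) < 0.1:
        raise RuntimeError(
            f"sampler failed to mix (acceptance rates {accept_rates}); settings: {settings}"
        )
    return PosteriorFit(
        spec=spec,
        settings=settings,
        term_names=spec.term_names,
        individuals=individuals,
        samples=samples,
        draws=all_draws,
        accept_rates=accept_rates,
        n_divergent=n_div,
    )


# ---------------------------------------------------------------------------
# summaries and diagnostics


def summarize(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior mean, SD, central 95% interval, Rhat and a significance flag.

    The significance flag (95% CI excludes zero) is reported for fixed
    effects only; it is vacuous for the strictly positive SD/precision
    parameters and left NA there.
    """
    rhats = _rhat_named(fit.named_draws())
    rows = []
    for name, d in fit.named_draws().items():
        flat = d.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        sig = (lo > 0) or (hi < 0) if name in fit.term_names else pd.NA
        rows.append(
            {
                "term": name,
                "estimate": float(flat.mean()),
                "est_error": float(flat.std(ddof=1)),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": rhats[name],
                "significant": sig,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def _rhat_named(named: dict[str, np.ndarray]) -> dict[str, float]:
    import arviz as az

    ds = az.convert_to_dataset({k: v for k, v in named.items()})
    r = az.rhat(ds)
    return {k: float(r[k].values) for k in named}


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    threshold: float
    passed: bool
    failing: list[str] = field(default_factory=list)


def check_convergence(
    fit: PosteriorFit, rhat_threshold: float = 1.05, plot_dir=None
) -> ConvergenceReport:
    """Split-Rhat per named parameter; passes iff all are below the threshold.

    With ``plot_dir`` set, writes one trace plot per parameter for visual
    inspection.
    """
    if fit.draws.shape[0] < 2:
        raise ValueError("Rhat requires at least two chains")
    named = fit.named_draws()
    rhats = _rhat_named(named)
    failing = [k for k, v in rhats.items() if not (v < rhat_threshold)]
    if plot_dir is not None:
        _write_trace_plots(named, plot_dir)
    return ConvergenceReport(
        rhat=rhats, threshold=rhat_threshold, passed=not failing, failing=failing
    )


def _write_trace_plots(named: dict[str, np.ndarray], plot_dir) -> None:
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(plot_dir, exist_ok=True)
    for name, d in named.items():
        fig, ax = plt.subplots(figsize=(6, 2.5))
        for c in range(d.shape[0]):
            ax.plot(d[c], lw=0.5)
        ax.set_title(name)
        safe = name.replace(":", "_x_")
        fig.savefig(os.path.join(plot_dir, f"trace_{safe}.png"), dpi=100)
        plt.close(fig)


def stratum_effect(main, interaction=None, level: int = 1):
    """Effect of a term at a given level of a binary modifier.

    effect(level) = main + level * interaction, evaluated draw-wise when the
    inputs are draw arrays (returning (mean, q2.5, q97.5)) or directly when
    they are scalars (returning a float). A missing interaction returns the
    main effect unchanged.
    """
    if interaction is None:
        interaction = 0.0
    main = np.asarray(main, dtype=float)
    eff = main + level * np.asarray(interaction, dtype=float)
    if eff.ndim == 0:
        return float(eff)
    flat = eff.reshape(-1)
    lo, hi = np.quantile(flat, [0.025, 0.975])
    return float(flat.mean()), float(lo), float(hi)


def stratum_effect_from_fit(fit: PosteriorFit, main: str, modifier: str, level: int):
    """Draw-wise stratum effect for a fitted model (true posterior interval)."""
    inter_name = f"{main}:{modifier}"
    if inter_name not in fit.term_names:
        inter_name_rev = f"{modifier}:{main}"
        inter_name = inter_name_rev if inter_name_rev in fit.term_names else None
    inter = fit.coef_draws(inter_name) if inter_name else None
    return stratum_effect(fit.coef_draws(main), inter, level)


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index_label="term")
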