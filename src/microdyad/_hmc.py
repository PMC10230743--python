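"""Minimal Hamiltonian Monte Carlo with step-size and mass adaptation.

A self-contained gradient-based MCMC kernel used by the dyadic Beta model:
leapfrog integration with a jittered step count, dual-averaging step-size
adaptation toward a target acceptance rate (Nesterov/dual averaging as used
by adaptive HMC samplers), and one diagonal mass-matrix update from draws
collected mid-warmup. The log density must supply analytic gradients.

Numerical choices: divergences (non-finite or > 1000 energy error) are
rejected outright; the trajectory length is capped to bound cost; all
randomness flows through one numpy Generator so seeded runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HmcChainResult:
    draws: np.ndarray          # (n_draws, dim)
    accept_rate: float
    n_divergent: int
    step_size: float


def _leapfrog(logp_grad, x, p, eps, n_steps, minv):
    lp, g = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        x = x + eps * (minv * p)
        lp, g = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, g
        p = p + 0.5 * eps * g
    return x, p, lp, g


def _find_initial_step(logp_grad, x0, minv, rng):
    """Crude bisection toward ~50% acceptance for one leapfrog step."""
    eps = 0.1
    lp0, _ = logp_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(minv)
    h0 = lp0 - 0.5 * np.sum(minv * p0 * p0)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x0, p0, eps, 1, minv)
    h1 = lp1 - 0.5 * np.sum(minv * p1 * p1) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        x1, p1, lp1, _ = _leapfrog(logp_grad, x0, p0, eps, 1, minv)
        h1 = lp1 - 0.5 * np.sum(minv * p1 * p1) if np.isfinite(lp1) else -np.inf
        if direction > 0 and (h1 - h0) <= np.log(0.5):
            break
        if direction < 0 and (h1 - h0) > np.log(0.5):
            break
    return max(eps, 1e-8)


def sample_chain(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    traj_len: float = 0.8,
    max_leapfrog: int = 32,
) -> HmcChainResult:
    """Run one HMC chain; returns post-warmup draws."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    minv = np.ones(dim)  # inverse mass (posterior-variance estimate)

    eps = _find_initial_step(logp_grad, x, minv, rng)
    # dual-averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass adaptation window: draws from [0.25w, 0.75w), applied at 0.75w
    w_lo, w_hi = int(0.25 * n_warmup), int(0.75 * n_warmup)
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_acc = 0
    n_div = 0
    adapt_iter = 0  # resets when the mass matrix changes
    total = n_warmup + n_draws

    for it in range(total):
        adapting = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(minv)
        lp0, _ = logp_grad(x)
        h0 = lp0 - 0.5 * np.sum(minv * p0 * p0)

        n_steps = max(1, min(max_leapfrog, int(round(traj_len / eps))))
        n_steps = max(1, int(round(n_steps * rng.uniform(0.75, 1.25))))
        n_steps = min(n_steps, max_leapfrog)

        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, n_steps, minv)
        h1 = lp1 - 0.5 * np.sum(minv * p1 * p1) if np.isfinite(lp1) else -np.inf
        delta_h = h1 - h0
        if not np.isfinite(delta_h) or delta_h < -1000.0:
            accept_prob = 0.0
            n_div += 1
        else:
            accept_prob = min(1.0, float(np.exp(min(delta_h, 0.0))))
        if rng.uniform() < accept_prob:
            x = x1
            if not adapting:
                n_acc += 1

        if adapting:
            adapt_iter += 1
            m = adapt_iter
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_lo <= it < w_hi:
                window.append(x.copy())
            if it == w_hi - 1 and len(window) >= 10:
                arr = np.asarray(window)
                var = arr.var(axis=0, ddof=1)
                k = arr.shape[0]
                # Stan-style shrinkage toward a small regularising value
                minv = (k / (k + 5.0)) * var + (5.0 / (k + 5.0)) * 1e-3
                minv = np.maximum(minv, 1e-8)
                eps = _find_initial_step(logp_grad, x, minv, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
                adapt_iter = 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x

    return HmcChainResult(
        draws=draws,
        accept_rate=n_acc / max(n_draws, 1),
        n_divergent=n_div,
        step_size=eps,
    )
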