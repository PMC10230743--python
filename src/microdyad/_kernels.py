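"""Numba-compiled log-posterior/gradient kernel for the dyadic Beta model.

Numerically identical (to floating-point roundoff) to the pure-numpy
closure in :mod:`microdyad.model`; exists because the HMC sampler evaluates
the gradient tens of thousands of times per fit and the attribution scan
runs hundreds of fits. The numpy implementation remains the reference and
the two are cross-checked in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _digamma(x: float) -> float:
    # recurrence to x >= 6, then the standard asymptotic series
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    f = 1.0 / (x * x)
    s = f * (
        1.0 / 12.0
        - f * (1.0 / 120.0 - f * (1.0 / 252.0 - f * (1.0 / 240.0 - f * (1.0 / 132.0))))
    )
    return r + math.log(x) - 0.5 / x - s


@njit(cache=False)
def _core(theta, X, ly, l1y, logit_y, ia, ib, sa, sb, nu, nw,
          coef_var, nu_t, s_t, a0, b0):
    n, p = X.shape
    beta = theta[:p]
    u = theta[p : p + nu]
    w = theta[p + nu : p + nu + nw]
    lsu = theta[p + nu + nw]
    lsw = theta[p + nu + nw + 1]
    lphi = theta[p + nu + nw + 2]
    su = math.exp(lsu)
    sw = math.exp(lsw)
    phi = math.exp(lphi)
    grad = np.zeros_like(theta)
    if not math.isfinite(phi) or phi > 1e8 or phi < 1e-10 or su < 1e-10 or sw < 1e-10:
        return -np.inf, grad

    lgam_phi = math.lgamma(phi)
    dig_phi = _digamma(phi)
    ll = 0.0
    dphi = 0.0
    for d in range(n):
        eta = u[ia[d]] + u[ib[d]] + w[sa[d]] + w[sb[d]]
        for j in range(p):
            eta += X[d, j] * beta[j]
        mu = 1.0 / (1.0 + math.exp(-eta))
        a = mu * phi
        b = (1.0 - mu) * phi
        if a <= 0.0 or b <= 0.0:
            return -np.inf, grad
        ll += lgam_phi - math.lgamma(a) - math.lgamma(b) \
            + (a - 1.0) * ly[d] + (b - 1.0) * l1y[d]
        dig_a = _digamma(a)
        dig_b = _digamma(b)
        g = phi * mu * (1.0 - mu) * (dig_b - dig_a + logit_y[d])
        for j in range(p):
            grad[j] += g * X[d, j]
        grad[p + ia[d]] += g
        grad[p + ib[d]] += g
        grad[p + nu + sa[d]] += g
        grad[p + nu + sb[d]] += g
        dphi += dig_phi - mu * dig_a - (1.0 - mu) * dig_b \
            + mu * ly[d] + (1.0 - mu) * l1y[d]

    lp = ll
    uu = 0.0
    for i in range(nu):
        uu += u[i] * u[i]
        grad[p + i] -= u[i] / (su * su)
    ww = 0.0
    for i in range(nw):
        ww += w[i] * w[i]
        grad[p + nu + i] -= w[i] / (sw * sw)
    bb = 0.0
    for j in range(p):
        bb += beta[j] * beta[j]
        grad[j] -= beta[j] / coef_var
    lp += -0.5 * bb / coef_var
    lp += -0.5 * uu / (su * su) - nu * lsu
    lp += -0.5 * ww / (sw * sw) - nw * lsw

    qsu = su * su / (nu_t * s_t * s_t)
    qsw = sw * sw / (nu_t * s_t * s_t)
    lp += -0.5 * (nu_t + 1.0) * math.log1p(qsu) + lsu
    lp += -0.5 * (nu_t + 1.0) * math.log1p(qsw) + lsw
    lp += a0 * lphi - b0 * phi

    grad[p + nu + nw] = uu / (su * su) - nu - (nu_t + 1.0) * qsu / (1.0 + qsu) + 1.0
    grad[p + nu + nw + 1] = ww / (sw * sw) - nw - (nu_t + 1.0) * qsw / (1.0 + qsw) + 1.0
    grad[p + nu + nw + 2] = phi * dphi + a0 - b0 * phi
    return lp, grad


def make_logp_grad_compiled(y, X, ia, ib, sa, sb, nu, nw, priors):
    """Compiled counterpart of ``model._make_logp_grad`` (same contract)."""
    ly = np.log(y)
    l1y = np.log1p(-y)
    logit_y = ly - l1y
    X = np.ascontiguousarray(X, dtype=np.float64)
    ia = np.ascontiguousarray(ia, dtype=np.int64)
    ib = np.ascontiguousarray(ib, dtype=np.int64)
    sa = np.ascontiguousarray(sa, dtype=np.int64)
    sb = np.ascontiguousarray(sb, dtype=np.int64)
    coef_var = priors.coef_sd ** 2

    def logp_grad(theta):
        return _core(theta, X, ly, l1y, logit_y, ia, ib, sa, sb, nu, nw,
                     coef_var, priors.sd_df, priors.sd_scale,
                     priors.phi_shape, priors.phi_rate)

    return logp_grad
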