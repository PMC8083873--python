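"""Numba inner loops for the Gibbs samplers.

All inverse-gamma draws use the reciprocal-gamma construction
``IG(shape, rate) = rate / Gamma(shape, 1)``; the gamma variates are
pre-drawn per sweep by the (numpy ``Generator``-driven) Python driver and
consumed here, so a chain is a pure function of its seed.  Rates are
clamped to >= 1e-300 and local variances to [1e-12, 1e12] to keep the
heavy Horseshoe tails finite in double precision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RATE_MIN = 1e-300
LAM2_MIN = 1e-12
LAM2_MAX = 1e12


@njit(cache=True)
def _ig(rate: float, gamma_var: float) -> float:
    """Inverse-gamma draw from a pre-drawn unit-rate gamma variate."""
    r = rate if rate > RATE_MIN else RATE_MIN
    return r / gamma_var


@njit(cache=True)
def _clamp_var(x: float) -> float:
    if x < LAM2_MIN:
        return LAM2_MIN
    if x > LAM2_MAX:
        return LAM2_MAX
    return x


@njit(cache=True)
def beta_params(s: float, xwx: float, prior_var: float, sig2e: float):
    """Mean and sd of the Gaussian full conditional of one marker effect.

    ``s`` is the weighted cross-product x_k' W r with r the residuals
    *excluding* marker k, ``xwx`` = x_k' W x_k.
    """
    prec = xwx / sig2e + 1.0 / prior_var
    mean = (s / sig2e) / prec
    sd = 1.0 / np.sqrt(prec)
    return mean, sd


@njit(cache=True)
def bayesU_local_rates(beta_k: float, tau2: float, lam2_k: float, nu_k: float):
    """IG rates for (lambda_k^2 | .) and (nu_k | .); both shapes are 1."""
    rate_lam2 = 1.0 / nu_k + beta_k * beta_k / (2.0 * tau2)
    rate_nu = 1.0 + 1.0 / lam2_k
    return rate_lam2, rate_nu


@njit(cache=True)
def bayesHP_local_rates(beta_k, tau2, lam2_k, theta_k, eta2_k, nu_k):
    """IG rates for the Horseshoe+ chain lambda^2, theta, eta^2, nu (shapes all 1)."""
    rate_lam2 = 1.0 / theta_k + beta_k * beta_k / (2.0 * tau2)
    rate_theta = 1.0 / eta2_k + 1.0 / lam2_k
    rate_eta2 = 1.0 / nu_k + 1.0 / theta_k
    rate_nu = 1.0 + 1.0 / eta2_k
    return rate_lam2, rate_theta, rate_eta2, rate_nu


@njit(cache=True)
def bayesHE_local_rates(beta_k, tau2, lam2_k, theta_k, upsilon):
    """IG rates for the half-t chain: lambda^2 has shape (upsilon+1)/2,
    theta has shape (upsilon+1)/2."""
    rate_lam2 = upsilon / theta_k + beta_k * beta_k / (2.0 * tau2)
    rate_theta = 1.0 + upsilon / lam2_k
    return rate_lam2, rate_theta


@njit(cache=True)
def _marker_draw(X, wx, resid, beta, xwx, k, prior_var, sig2e, z):
    """Draw beta_k and update residuals in place; returns the new beta_k."""
    n = resid.shape[0]
    s = xwx[k] * beta[k]
    for i in range(n):
        s += wx[i, k] * resid[i]
    mean, sd = beta_params(s, xwx[k], prior_var, sig2e)
    new_b = mean + sd * z
    diff = beta[k] - new_b
    for i in range(n):
        resid[i] += X[i, k] * diff
    return new_b


@njit(cache=True)
def sweep_markers_bayesU(X, wx, resid, beta, xwx, lam2, nu, tau2, sig2e, z, g_lam, g_nu):
    m = beta.shape[0]
    for k in range(m):
        prior_var = _clamp_var(lam2[k] * tau2)
        beta[k] = _marker_draw(X, wx, resid, beta, xwx, k, prior_var, sig2e, z[k])
        r_lam, _ = bayesU_local_rates(beta[k], tau2, lam2[k], nu[k])
        lam2[k] = _clamp_var(_ig(r_lam, g_lam[k]))
        _, r_nu = bayesU_local_rates(beta[k], tau2, lam2[k], nu[k])
        nu[k] = _ig(r_nu, g_nu[k])


@njit(cache=True)
def sweep_markers_bayesHP(X, wx, resid, beta, xwx, lam2, theta, eta2, nu,
                          tau2, sig2e, z, g_lam, g_th, g_eta, g_nu):
    m = beta.shape[0]
    for k in range(m):
        prior_var = _clamp_var(lam2[k] * tau2)
        beta[k] = _marker_draw(X, wx, resid, beta, xwx, k, prior_var, sig2e, z[k])
        r_lam, _, _, _ = bayesHP_local_rates(beta[k], tau2, lam2[k], theta[k], eta2[k], nu[k])
        lam2[k] = _clamp_var(_ig(r_lam, g_lam[k]))
        _, r_th, _, _ = bayesHP_local_rates(beta[k], tau2, lam2[k], theta[k], eta2[k], nu[k])
        theta[k] = _clamp_var(_ig(r_th, g_th[k]))
        _, _, r_eta, _ = bayesHP_local_rates(beta[k], tau2, lam2[k], theta[k], eta2[k], nu[k])
        eta2[k] = _clamp_var(_ig(r_eta, g_eta[k]))
        _, _, _, r_nu = bayesHP_local_rates(beta[k], tau2, lam2[k], theta[k], eta2[k], nu[k])
        nu[k] = _ig(r_nu, g_nu[k])


@njit(cache=True)
def sweep_markers_bayesHE(X, wx, resid, beta, xwx, lam2, theta,
                          tau2, upsilon, sig2e, z, g_lam, g_th):
    m = beta.shape[0]
    for k in range(m):
        prior_var = _clamp_var(lam2[k] * tau2)
        beta[k] = _marker_draw(X, wx, resid, beta, xwx, k, prior_var, sig2e, z[k])
        r_lam, _ = bayesHE_local_rates(beta[k], tau2, lam2[k], theta[k], upsilon)
        lam2[k] = _clamp_var(_ig(r_lam, g_lam[k]))
        _, r_th = bayesHE_local_rates(beta[k], tau2, lam2[k], theta[k], upsilon)
        theta[k] = _clamp_var(_ig(r_th, g_th[k]))


@njit(cache=True)
def bayesB_inclusion_logratio(s, xwx, prior_var, sig2e):
    """Log marginal-likelihood ratio (marker in / marker out) with the
    effect integrated out analytically."""
    t = sig2e + prior_var * xwx
    return -0.5 * np.log(t / sig2e) + 0.5 * prior_var * s * s / (sig2e * t)


@njit(cache=True)
def sweep_markers_bayesAB(X, wx, resid, beta, xwx, s2bk, delta, pi, df, s2_prior,
                          sig2e, z, g_post, g_prior, u):
    """BayesA (pi = 0) / BayesB marker loop with collapsed indicator sampling.

    Per marker: update the effect variance (posterior scaled-inv-chi^2 for
    included markers, prior draw for excluded ones), then the indicator
    with beta_k integrated out, then beta_k itself.
    """
    m = beta.shape[0]
    n = resid.shape[0]
    for k in range(m):
        if delta[k] == 1:
            s2bk[k] = _ig(0.5 * (df * s2_prior + beta[k] * beta[k]), g_post[k])
        else:
            s2bk[k] = _ig(0.5 * df * s2_prior, g_prior[k])
        prior_var = _clamp_var(s2bk[k])
        # cross-product against residuals with marker k removed
        s = xwx[k] * beta[k]
        for i in range(n):
            s += wx[i, k] * resid[i]
        if pi > 0.0:
            llr = bayesB_inclusion_logratio(s, xwx[k], prior_var, sig2e)
            # p(delta=1 | .) = (1-pi) e^llr / ((1-pi) e^llr + pi)
            if llr > 500.0:
                p1 = 1.0
            else:
                w1 = (1.0 - pi) * np.exp(llr)
                p1 = w1 / (w1 + pi)
            new_delta = 1 if u[k] < p1 else 0
        else:
            new_delta = 1
        if new_delta == 1:
            mean, sd = beta_params(s, xwx[k], prior_var, sig2e)
            new_b = mean + sd * z[k]
        else:
            new_b = 0.0
        diff = beta[k] - new_b
        if diff != 0.0:
            for i in range(n):
                resid[i] += X[i, k] * diff
        beta[k] = new_b
        delta[k] = new_delta
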