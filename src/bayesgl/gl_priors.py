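"""Conditional updates for the global-local shrinkage hierarchies.

The workhorse identity (half-Cauchy as a scale mixture of inverse gammas):
if ``x^2 ~ IG(1/2, 1/a)`` and ``a ~ IG(1/2, 1/A^2)`` then ``x ~ C+(0, A)``.
Chaining it once gives the Horseshoe local scale, twice the Horseshoe+
scale, and replacing the first layer's shape 1/2 by ``upsilon/2`` gives a
half-t local scale with ``upsilon`` degrees of freedom:

* Horseshoe (bayesU):   ``lam_k^2 ~ IG(1/2, 1/nu_k)``, ``nu_k ~ IG(1/2, 1)``
* Horseshoe+ (bayesHP): ``lam_k^2 ~ IG(1/2, 1/theta_k)``,
  ``theta_k ~ IG(1/2, 1/eta_k^2)``, ``eta_k^2 ~ IG(1/2, 1/nu_k)``,
  ``nu_k ~ IG(1/2, 1)``
* half-t (bayesHE):     ``lam_k^2 ~ IG(upsilon/2, upsilon/theta_k)``,
  ``theta_k ~ IG(1/2, 1)``, ``upsilon ~ Gamma(a, b)`` (b a rate)

and in both bayesHP and bayesHE the global scale is
``tau^2 ~ IG(1/2, 1/xi)``, ``xi ~ IG(1/2, N^2)``, i.e. ``tau ~ C+(0, 1/N)``
with ``N`` the training-set size.  BayesU instead takes a flat prior on
``tau`` itself, so its tau^2 conditional carries a ``(tau^2)^(-1/2)``
transform factor.  All conditionals below are inverse gammas in the repo's
IG(shape, rate) convention; every derived (shape, rate) pair is pinned to
a grid-integration oracle in the test suite.

``upsilon`` has no conjugate conditional; it is sampled by random-walk
Metropolis-Hastings on ``zeta = log(upsilon)`` whose target includes the
``exp(zeta)`` Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import _kernels as K

#: Support clamp for the half-t degrees of freedom: Gamma(upsilon/2)
#: under/overflows far outside this range, which is itself far outside
#: any plausible df.
UPSILON_MIN = 0.05
UPSILON_MAX = 200.0


def _ig_draw(shape: float, rate: float, rng: np.random.Generator) -> float:
    return max(rate, K.RATE_MIN) / rng.gamma(shape)


def _clamp(x: float) -> float:
    return min(max(x, K.LAM2_MIN), K.LAM2_MAX)


# ---------------------------------------------------------------------------
# BayesU (Horseshoe)
# ---------------------------------------------------------------------------

def update_locals_bayesU(state, k: int, rng: np.random.Generator):
    """Draw lam_k^2 ~ IG(1, 1/nu_k + beta_k^2/(2 tau^2)) then
    nu_k ~ IG(1, 1 + 1/lam_k^2)."""
    r_lam, _ = K.bayesU_local_rates(state.beta[k], state.tau2,
                                    state.lam2[k], state.nu_aux[k])
    state.lam2[k] = _clamp(_ig_draw(1.0, r_lam, rng))
    _, r_nu = K.bayesU_local_rates(state.beta[k], state.tau2,
                                   state.lam2[k], state.nu_aux[k])
    state.nu_aux[k] = _ig_draw(1.0, r_nu, rng)
    return state


def update_global_bayesU(state, rng: np.random.Generator):
    """Flat-on-tau global update: tau^2 ~ IG((m-1)/2, S/2), S = sum beta_k^2/lam_k^2.

    The conditional is improper for m = 1; for numerically vanishing S the
    draw is floored rather than collapsing the chain.
    """
    m = state.beta.size
    if m < 2:
        raise ValueError("flat-tau conditional is improper for m < 2")
    S = float(np.sum(state.beta**2 / state.lam2))
    state.tau2 = _clamp(_ig_draw(0.5 * (m - 1.0), 0.5 * S, rng))
    return state


# ---------------------------------------------------------------------------
# BayesHP (Horseshoe+)
# ---------------------------------------------------------------------------

def update_locals_bayesHP(state, k: int, rng: np.random.Generator):
    """Chained IG draws for lam_k^2, theta_k, eta_k^2, nu_k (all shape 1)."""
    b, t2 = state.beta[k], state.tau2
    r_lam, _, _, _ = K.bayesHP_local_rates(b, t2, state.lam2[k], state.theta[k],
                                           state.eta2[k], state.nu_aux[k])
    state.lam2[k] = _clamp(_ig_draw(1.0, r_lam, rng))
    _, r_th, _, _ = K.bayesHP_local_rates(b, t2, state.lam2[k], state.theta[k],
                                          state.eta2[k], state.nu_aux[k])
    state.theta[k] = _clamp(_ig_draw(1.0, r_th, rng))
    _, _, r_eta, _ = K.bayesHP_local_rates(b, t2, state.lam2[k], state.theta[k],
                                           state.eta2[k], state.nu_aux[k])
    state.eta2[k] = _clamp(_ig_draw(1.0, r_eta, rng))
    _, _, _, r_nu = K.bayesHP_local_rates(b, t2, state.lam2[k], state.theta[k],
                                          state.eta2[k], state.nu_aux[k])
    state.nu_aux[k] = _ig_draw(1.0, r_nu, rng)
    return state


def update_global_halfcauchy(state, rng: np.random.Generator):
    """Global scale under tau ~ C+(0, 1/N) (bayesHP and bayesHE):
    tau^2 ~ IG((m+1)/2, 1/xi + S/2), then xi ~ IG(1, N^2 + 1/tau^2)."""
    m = state.beta.size
    S = float(np.sum(state.beta**2 / state.lam2))
    state.tau2 = _clamp(_ig_draw(0.5 * (m + 1.0), 1.0 / state.xi + 0.5 * S, rng))
    state.xi = _ig_draw(1.0, float(state.N) ** 2 + 1.0 / state.tau2, rng)
    return state


#: spec name for the Horseshoe+ global update (shared with bayesHE)
update_global_bayesHP = update_global_halfcauchy


# ---------------------------------------------------------------------------
# BayesHE (half-t with unknown degrees of freedom)
# ---------------------------------------------------------------------------

def update_locals_bayesHE(state, k: int, rng: np.random.Generator):
    """Draw lam_k^2 ~ IG((upsilon+1)/2, upsilon/theta_k + beta_k^2/(2 tau^2))
    then theta_k ~ IG((upsilon+1)/2, 1 + upsilon/lam_k^2)."""
    ups = state.upsilon
    r_lam, _ = K.bayesHE_local_rates(state.beta[k], state.tau2, state.lam2[k],
                                     state.theta[k], ups)
    state.lam2[k] = _clamp(_ig_draw(0.5 * (ups + 1.0), r_lam, rng))
    _, r_th = K.bayesHE_local_rates(state.beta[k], state.tau2, state.lam2[k],
                                    state.theta[k], ups)
    state.theta[k] = _clamp(_ig_draw(0.5 * (ups + 1.0), r_th, rng))
    return state


def log_conditional_df(upsilon: float, theta: np.ndarray, lambda2: np.ndarray,
                       a: float, b: float, m: int | None = None) -> float:
    """Log full-conditional kernel of the half-t degrees of freedom.

    ``(upsilon*m/2 + a - 1) log(upsilon) - m log Gamma(upsilon/2)
    - upsilon * (1/2 sum log(theta_k lam_k^2) + sum 1/(theta_k lam_k^2) + b)``

    up to an additive constant; reduces to the Gamma(a, b) log-kernel at
    m = 0.
    """
    theta = np.asarray(theta, dtype=float)
    lambda2 = np.asarray(lambda2, dtype=float)
    if m is None:
        m = theta.size
    if not (np.isfinite(upsilon) and upsilon > 0 and np.all(np.isfinite(theta))
            and np.all(np.isfinite(lambda2)) and a > 0 and b > 0):
        raise ValueError("log_conditional_df needs finite positive inputs")
    prod = theta[:m] * lambda2[:m]
    c = 0.5 * float(np.sum(np.log(prod))) + float(np.sum(1.0 / prod)) + b
    return ((upsilon * m / 2.0 + a - 1.0) * math.log(upsilon)
            - m * gammaln(upsilon / 2.0) - upsilon * c)


@dataclass
class DFSampleResult:
    """Outcome of one Metropolis-Hastings update of upsilon."""

    new_upsilon: float
    accepted: bool
    log_ratio: float

    def __post_init__(self):
        if self.new_upsilon <= 0:
            raise ValueError("upsilon must stay positive")


def sample_df_mh(state, a: float, b: float, mh_step: float,
                 rng: np.random.Generator) -> DFSampleResult:
    """One random-walk Metropolis-Hastings step on zeta = log(upsilon).

    The zeta-space target is the upsilon full conditional times the
    exp(zeta) Jacobian of the transform; proposals outside
    [UPSILON_MIN, UPSILON_MAX] are rejected.
    """
    ups = state.upsilon
    theta, lam2 = state.theta, state.lam2
    zeta = math.log(ups)
    zeta_new = zeta + mh_step * rng.standard_normal()
    ups_new = math.exp(zeta_new)
    if not (UPSILON_MIN <= ups_new <= UPSILON_MAX):
        return DFSampleResult(ups, False, -math.inf)
    # log target in zeta-space = log f(upsilon | .) + zeta (Jacobian)
    log_ratio = (log_conditional_df(ups_new, theta, lam2, a, b) + zeta_new
                 - log_conditional_df(ups, theta, lam2, a, b) - zeta)
    if math.log(rng.uniform()) < log_ratio:
        return DFSampleResult(ups_new, True, log_ratio)
    return DFSampleResult(ups, False, log_ratio)
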