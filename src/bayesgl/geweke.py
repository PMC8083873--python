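"""Joint-distribution (Geweke-style) validation of the Gibbs samplers.

Two samplers target the same joint law p(parameters, data):

* the *marginal-conditional* sampler draws parameters from their priors
  and data from the likelihood -- exact independent draws;
* the *successive-conditional* sampler alternates one full Gibbs sweep
  with a fresh data draw given the current parameters.

If the Gibbs conditionals are derived and coded correctly, both produce
the same marginal law for every parameter, so first and second moments
must agree within Monte-Carlo error.  A wrong conditional shows up as a
drifting successive-conditional chain.

The production chain uses improper priors on the intercept (flat) and
the residual variance (Jeffreys), which cannot be sampled from, so the
rig switches on the proper options: mu ~ N(0, 1) and
sigma_e^2 ~ IG(4, 3).  BayesU's flat-on-tau global scale is likewise
improper and is held fixed here; the half-Cauchy C+(0, 1/N) global prior
of the other families has no finite moments, so the rig compares moments
of log tau^2 (and log sigma_e^2), which are finite and well behaved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .chain_core import ModelSpec, SamplerState, fast_sweep, init_state
from .genio import GenotypeMatrix, PhenotypeTable

MU_PRIOR = (0.0, 1.0)          # normal(mean, variance)
SIGMA2E_PRIOR = (4.0, 3.0)     # IG(shape, rate): mean 1, finite variance
FIXED_TAU2_BAYESU = 0.5
S2_BETA_RIG = 0.1


def _clamp(x):
    return np.clip(x, K.LAM2_MIN, K.LAM2_MAX)


def _ig(shape, rate, rng, size=None):
    return np.maximum(rate, K.RATE_MIN) / rng.gamma(shape, size=size)


def prior_draw(state: SamplerState, rng: np.random.Generator) -> None:
    """Overwrite the state's latents with one exact draw from the prior."""
    spec, m = state.spec, state.m
    state.mu = MU_PRIOR[0] + math.sqrt(MU_PRIOR[1]) * rng.standard_normal()
    state.sigma2_e = float(_ig(*SIGMA2E_PRIOR, rng))
    fam = spec.family
    if fam in ("bayesU", "bayesHP", "bayesHE"):
        if fam == "bayesU":
            state.tau2 = spec.fixed_tau2
            state.nu_aux = _ig(0.5, 1.0, rng, m)
            state.lam2 = _clamp(_ig(0.5, 1.0 / state.nu_aux, rng, m))
        elif fam == "bayesHP":
            state.nu_aux = _ig(0.5, 1.0, rng, m)
            state.eta2 = _clamp(_ig(0.5, 1.0 / state.nu_aux, rng, m))
            state.theta = _clamp(_ig(0.5, 1.0 / state.eta2, rng, m))
            state.lam2 = _clamp(_ig(0.5, 1.0 / state.theta, rng, m))
            state.xi = float(_ig(0.5, float(state.N) ** 2, rng))
            state.tau2 = float(_clamp(_ig(0.5, 1.0 / state.xi, rng)))
        else:  # bayesHE
            ups = float(rng.gamma(spec.a) / spec.b)
            state.upsilon = min(max(ups, 0.05), 200.0)
            state.theta = _clamp(_ig(0.5, 1.0, rng, m))
            state.lam2 = _clamp(_ig(0.5 * state.upsilon,
                                    state.upsilon / state.theta, rng, m))
            state.xi = float(_ig(0.5, float(state.N) ** 2, rng))
            state.tau2 = float(_clamp(_ig(0.5, 1.0 / state.xi, rng)))
        sd = np.sqrt(_clamp(state.lam2 * state.tau2))
        state.beta = sd * rng.standard_normal(m)
    else:  # bayesA / bayesB
        df, s2 = spec.df_ab, state.s2_beta
        state.sigma2_beta_k = _ig(0.5 * df, 0.5 * df * s2, rng, m)
        pi = spec.pi if fam == "bayesB" else 0.0
        state.delta = (rng.uniform(size=m) >= pi).astype(np.int64)
        state.beta = (state.delta
                      * np.sqrt(state.sigma2_beta_k) * rng.standard_normal(m))
    state.refresh_residuals()


def regenerate_data(state: SamplerState, rng: np.random.Generator) -> None:
    """Draw y ~ N(mu + X beta, sigma_e^2 D) and refresh the residuals."""
    noise = rng.standard_normal(state.n) * np.sqrt(state.sigma2_e / state.w)
    state.y = state.mu + state.X @ state.beta + noise
    state.refresh_residuals()


def _record(state: SamplerState) -> tuple:
    return (state.mu, math.log(state.sigma2_e), math.log(state.tau2))


_NAMES = ("mu", "log_sigma2_e", "log_tau2")


def batch_means_se(x: np.ndarray, n_batches: int = 50) -> float:
    """Standard error of the mean of an autocorrelated series (batch means)."""
    x = np.asarray(x, dtype=float)
    b = max(len(x) // n_batches, 1)
    nb = len(x) // b
    means = x[: nb * b].reshape(nb, b).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(nb))


@dataclass
class GewekeResult:
    """Moment comparison between the two samplers."""

    table: pd.DataFrame      # quantity, moment, mc_mean, sc_mean, z
    max_abs_z: float

    def passed(self, z_max: float = 4.0) -> bool:
        return self.max_abs_z < z_max


def _rig_state(spec: ModelSpec, n: int, m: int, seed: int) -> SamplerState:
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, size=m)
    codes = rng.binomial(2, p, size=(n, m)).astype(float)
    # guard against accidentally monomorphic tiny columns
    codes[0] = 0.0
    codes[1] = 2.0
    g = GenotypeMatrix([f"i{i}" for i in range(n)], [f"m{j}" for j in range(m)], codes)
    ph = PhenotypeTable(list(g.individual_ids), rng.standard_normal(n))
    return init_state(g, ph, spec, None)


def geweke_test(family: str, n: int = 10, m: int = 5, n_mc: int = 20_000,
                n_sc: int = 20_000, thin_sc: int = 2, seed: int = 0,
                a: float = 4.0, b: float = 1.0) -> GewekeResult:
    """Run both samplers for one prior family and compare moments.

    Returns z-scores for the first and second moments of mu,
    log sigma_e^2 and (families with a sampled global scale) log tau^2.
    """
    spec = ModelSpec(family=family, a=a, b=b, s2_beta=S2_BETA_RIG,
                     mu_prior=MU_PRIOR, sigma2e_prior=SIGMA2E_PRIOR,
                     adapt_mh=False,
                     fixed_tau2=FIXED_TAU2_BAYESU if family == "bayesU" else None)
    track_tau = family in ("bayesHP", "bayesHE")
    names = _NAMES[: 3 if track_tau else 2]

    rng = np.random.default_rng(seed + 1)
    state = _rig_state(spec, n, m, seed)
    mc = np.empty((n_mc, len(names)))
    for i in range(n_mc):
        prior_draw(state, rng)
        mc[i] = _record(state)[: len(names)]

    rng2 = np.random.default_rng(seed + 2)
    state = _rig_state(spec, n, m, seed)
    prior_draw(state, rng2)
    sc = np.empty((n_sc, len(names)))
    for i in range(n_sc * thin_sc):
        regenerate_data(state, rng2)
        fast_sweep(state, rng2)
        if (i + 1) % thin_sc == 0:
            sc[(i + 1) // thin_sc - 1] = _record(state)[: len(names)]

    rows = []
    for j, name in enumerate(names):
        for moment in (1, 2):
            a_mc = mc[:, j] ** moment
            a_sc = sc[:, j] ** moment
            se = math.sqrt((a_mc.std(ddof=1) / math.sqrt(n_mc)) ** 2
                           + batch_means_se(a_sc) ** 2)
            z = (a_mc.mean() - a_sc.mean()) / se
            rows.append({"quantity": name, "moment": moment,
                         "mc_mean": a_mc.mean(), "sc_mean": a_sc.mean(), "z": z})
    table = pd.DataFrame(rows)
    return GewekeResult(table, float(table["z"].abs().max()))
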