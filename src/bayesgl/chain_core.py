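"""Shared Gibbs-sampling engine for the Bayesian marker-regression families.

The model is ``y = mu*1 + X beta + e`` with ``e ~ N(0, D sigma_e^2)``,
``D = diag(d_ii)`` and ``d_ii = (1 - r_i^2)/r_i^2`` when the response is a
de-regressed proof with reliability ``r_i^2`` (``d_ii = 1`` otherwise).
The prior families differ only in the conditional variance they place on
each marker effect:

* ``bayesU``    -- Horseshoe: ``beta_k ~ N(0, lam_k^2 tau^2)``,
  ``lam_k ~ C+(0,1)``, flat prior on ``tau``.
* ``bayesHP``   -- Horseshoe+: a second half-Cauchy layer on the local
  scale; ``tau ~ C+(0, 1/N)`` with N the training size.
* ``bayesHE``   -- half-t local prior with unknown degrees of freedom
  ``upsilon ~ Gamma(a, b)``, sampled by random-walk Metropolis-Hastings
  on ``log(upsilon)``.
* ``bayesA``/``bayesB`` -- scaled-t / spike-and-t per-marker variances.

Inverse-gamma notation is fixed repo-wide as IG(shape, rate) with density
proportional to ``x^(-shape-1) exp(-rate/x)``.  Default priors on the
nuisance parameters are flat on ``mu`` and Jeffreys (``1/sigma_e^2``) on
the residual variance; both can be made proper (normal / inverse-gamma)
through :class:`ModelSpec`, which the sampler-validation rig relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels as K
from .genio import GenotypeMatrix, PhenotypeTable

FAMILIES = ("bayesA", "bayesB", "bayesU", "bayesHP", "bayesHE", "gblup")


@dataclass
class ModelSpec:
    """Prior family plus its hyperparameters.

    Parameters
    ----------
    family : str
        One of ``bayesA, bayesB, bayesU, bayesHP, bayesHE, gblup``.
    pi : float
        BayesB probability that a marker effect is exactly zero
        (default 0.95; BayesA is the ``pi = 0`` special case).
    a, b : float
        Shape and rate of the Gamma prior on the half-t degrees of
        freedom ``upsilon`` (bayesHE); prior mean a/b.
    df_ab, s2_beta : float
        Degrees of freedom and scale of the scaled-t prior for
        bayesA/bayesB.  ``s2_beta=None`` picks the scale so the prior
        genetic variance is ``h2_prior`` of the response variance.
    mh_step : float
        Initial sd of the random-walk proposal on ``log(upsilon)``.
    """

    family: str
    pi: float = 0.95
    a: float = 4.0
    b: float = 1.0
    df_ab: float = 4.2
    s2_beta: Optional[float] = None
    h2_prior: float = 0.5
    mh_step: float = 0.5
    adapt_mh: bool = True
    # optional proper priors (None => flat mu / Jeffreys sigma_e^2)
    mu_prior: Optional[tuple] = None          # (mean, variance)
    sigma2e_prior: Optional[tuple] = None     # (shape, rate)
    fixed_tau2: Optional[float] = None        # hold tau^2 fixed (validation rig)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 <= self.pi < 1.0:
            raise ValueError("pi must lie in [0, 1)")
        if self.a <= 0 or self.b <= 0 or self.df_ab <= 0 or self.mh_step <= 0:
            raise ValueError("a, b, df_ab, mh_step must be positive")
        if self.s2_beta is not None and self.s2_beta <= 0:
            raise ValueError("s2_beta must be positive")


@dataclass
class ChainConfig:
    """MCMC chain length control (defaults: 50,000 sweeps, 20,000 burn-in,
    thinning stride 50, i.e. 600 saved samples)."""

    n_iter: int = 50_000
    burn_in: int = 20_000
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.burn_in) / self.thin < 10:
            raise ValueError("chain too short: fewer than 10 saved samples")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


FAST_PRESET = dict(n_iter=5_000, burn_in=2_000, thin=10)


@dataclass
class SamplerState:
    """All latent quantities of one chain plus fixed data products."""

    # fixed data
    X: np.ndarray          # centered genotype codes, n x m
    wx: np.ndarray         # W X (precision-weighted columns)
    w: np.ndarray          # 1/d_ii
    y: np.ndarray
    xwx: np.ndarray        # x_k' W x_k per marker
    N: int                 # training size (half-Cauchy global scale 1/N)
    spec: ModelSpec
    # latents
    mu: float = 0.0
    beta: np.ndarray = None
    resid: np.ndarray = None
    lam2: np.ndarray = None
    theta: np.ndarray = None
    eta2: np.ndarray = None
    nu_aux: np.ndarray = None
    tau2: float = 1.0
    xi: float = 1.0
    upsilon: float = 1.0
    delta: np.ndarray = None
    sigma2_beta_k: np.ndarray = None
    sigma2_e: float = 1.0
    # bookkeeping
    s2_beta: float = 1.0       # resolved bayesA/B prior scale
    mh_log_step: float = 0.0
    mh_accepted: int = 0
    mh_proposals: int = 0

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def m(self) -> int:
        return self.beta.size

    def refresh_residuals(self):
        self.resid = self.y - self.mu - self.X @ self.beta

    def residual_drift(self) -> float:
        return float(np.max(np.abs(self.resid - (self.y - self.mu - self.X @ self.beta))))


@dataclass
class PosteriorSummary:
    """Posterior means and saved-draw traces of one chain."""

    beta_mean: np.ndarray
    mu_trace: np.ndarray
    vg_trace: np.ndarray
    sigma2e_trace: np.ndarray
    tau2_trace: np.ndarray
    upsilon_trace: Optional[np.ndarray]
    mu_mean: float
    sigma2_e_mean: float
    upsilon_mean: Optional[float]
    acceptance_rate: Optional[float]
    n_saved: int
    delta_mean: np.ndarray = None      # bayesB posterior inclusion frequency
    beta_trace: np.ndarray = None      # saved effect draws (optional)
    spec: ModelSpec = None
    config: ChainConfig = None
    train_freqs: np.ndarray = None

    def to_frame(self):
        import pandas as pd

        data = {"mu": self.mu_trace, "vg": self.vg_trace,
                "sigma2_e": self.sigma2e_trace, "tau2": self.tau2_trace}
        if self.upsilon_trace is not None:
            data["upsilon"] = self.upsilon_trace
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def center_genotypes(codes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Column-center additive codes by twice the (training) allele frequency."""
    return np.asarray(codes, dtype=float) - 2.0 * np.asarray(freqs, dtype=float)


def default_s2_beta(y, w, freqs, df_ab, h2_prior) -> float:
    """Scaled-t prior scale so the implied genetic variance is h2_prior*var(y)."""
    het = 2.0 * np.sum(freqs * (1.0 - freqs))
    vy = float(np.var(y, ddof=1))
    if het <= 0 or vy <= 0:
        raise ValueError("cannot calibrate s2_beta on monomorphic or constant data")
    if df_ab <= 2:
        raise ValueError("df_ab must exceed 2 for automatic s2_beta calibration")
    return h2_prior * vy * (df_ab - 2.0) / (df_ab * het)


def init_state(g: GenotypeMatrix, ph: PhenotypeTable, spec: ModelSpec,
               cfg: ChainConfig = None) -> SamplerState:
    """Build the initial sampler state from aligned genotype/phenotype data."""
    if spec.family == "gblup":
        raise ValueError("gblup is not a Gibbs family; use bayesgl.gblup")
    if list(g.individual_ids) != list(ph.individual_ids):
        raise ValueError("genotype and phenotype ids are not aligned "
                         "(use bayesgl.genio.align first)")
    codes = g.codes
    if not np.isfinite(codes).all():
        raise ValueError("genotypes contain missing calls; impute first")
    y = np.asarray(ph.y, dtype=float)
    w = 1.0 / np.asarray(ph.weight, dtype=float)
    X = np.ascontiguousarray(center_genotypes(codes, g.freqs))
    wx = np.ascontiguousarray(w[:, None] * X)
    xwx = np.einsum("ij,ij->j", X, wx)
    n, m = X.shape

    st = SamplerState(X=X, wx=wx, w=w, y=y, xwx=xwx, N=n, spec=spec)
    st.mu = float(np.average(y, weights=w))
    st.beta = np.zeros(m)
    st.resid = y - st.mu
    st.lam2 = np.ones(m)
    st.theta = np.ones(m)
    st.eta2 = np.ones(m)
    st.nu_aux = np.ones(m)
    st.tau2 = spec.fixed_tau2 if spec.fixed_tau2 is not None else 1.0
    st.xi = 1.0
    st.upsilon = spec.a / spec.b
    st.delta = np.ones(m, dtype=np.int64)
    st.sigma2_e = float(np.var(y, ddof=1))
    if st.sigma2_e <= 0:
        raise ValueError("response has zero variance")
    st.s2_beta = (spec.s2_beta if spec.s2_beta is not None
                  else default_s2_beta(y, w, g.freqs, spec.df_ab, spec.h2_prior))
    st.sigma2_beta_k = np.full(m, st.s2_beta)
    st.mh_log_step = math.log(spec.mh_step)
    return st


# ---------------------------------------------------------------------------
# elementary updates (spec op surface; also used by the validation rig)
# ---------------------------------------------------------------------------

def update_intercept(state: SamplerState, rng: np.random.Generator) -> SamplerState:
    """Gibbs draw of mu from its Gaussian full conditional (flat or normal prior)."""
    wsum = state.w.sum()
    prec = wsum / state.sigma2_e
    num = float(state.w @ (state.resid + state.mu)) / state.sigma2_e
    if state.spec.mu_prior is not None:
        m0, v0 = state.spec.mu_prior
        prec += 1.0 / v0
        num += m0 / v0
    new_mu = num / prec + rng.standard_normal() / math.sqrt(prec)
    state.resid += state.mu - new_mu
    state.mu = new_mu
    return state


def update_marker_effect(state: SamplerState, k: int, prior_var: float,
                         rng: np.random.Generator) -> SamplerState:
    """Gibbs draw of beta_k given its prior variance; O(n) residual update."""
    if prior_var <= 0:
        raise ValueError("prior_var must be positive")
    x_k = state.X[:, k]
    s = float(state.wx[:, k] @ state.resid) + state.xwx[k] * state.beta[k]
    mean, sd = K.beta_params(s, state.xwx[k], prior_var, state.sigma2_e)
    new_b = mean + sd * rng.standard_normal()
    state.resid += x_k * (state.beta[k] - new_b)
    state.beta[k] = new_b
    return state


def update_residual_variance(state: SamplerState, rng: np.random.Generator) -> SamplerState:
    """Inverse-gamma draw of sigma_e^2 with weighted residual sum of squares."""
    a0, g0 = state.spec.sigma2e_prior or (0.0, 0.0)
    shape = a0 + 0.5 * state.n
    rate = g0 + 0.5 * float(state.w @ (state.resid**2))
    state.sigma2_e = max(rate, K.RATE_MIN) / rng.gamma(shape)
    return state


# ---------------------------------------------------------------------------
# one full sweep (fast path; pre-drawn randomness consumed by numba kernels)
# ---------------------------------------------------------------------------

def fast_sweep(state: SamplerState, rng: np.random.Generator,
               adapt_t: int | None = None) -> SamplerState:
    """One full Gibbs sweep in the fixed update order:
    mu -> marker loop (effects with local scales) -> global scales ->
    upsilon (bayesHE) -> sigma_e^2.
    """
    from . import classic_priors, gl_priors

    spec, m = state.spec, state.m
    update_intercept(state, rng)
    z = rng.standard_normal(m)
    if spec.family == "bayesU":
        K.sweep_markers_bayesU(state.X, state.wx, state.resid, state.beta,
                               state.xwx, state.lam2, state.nu_aux,
                               state.tau2, state.sigma2_e,
                               z, rng.gamma(1.0, size=m), rng.gamma(1.0, size=m))
        if spec.fixed_tau2 is None:
            gl_priors.update_global_bayesU(state, rng)
    elif spec.family == "bayesHP":
        K.sweep_markers_bayesHP(state.X, state.wx, state.resid, state.beta,
                                state.xwx, state.lam2, state.theta, state.eta2,
                                state.nu_aux, state.tau2, state.sigma2_e, z,
                                rng.gamma(1.0, size=m), rng.gamma(1.0, size=m),
                                rng.gamma(1.0, size=m), rng.gamma(1.0, size=m))
        if spec.fixed_tau2 is None:
            gl_priors.update_global_halfcauchy(state, rng)
    elif spec.family == "bayesHE":
        sh = 0.5 * (state.upsilon + 1.0)
        K.sweep_markers_bayesHE(state.X, state.wx, state.resid, state.beta,
                                state.xwx, state.lam2, state.theta,
                                state.tau2, state.upsilon, state.sigma2_e, z,
                                rng.gamma(sh, size=m), rng.gamma(sh, size=m))
        if spec.fixed_tau2 is None:
            gl_priors.update_global_halfcauchy(state, rng)
        res = gl_priors.sample_df_mh(state, spec.a, spec.b,
                                     math.exp(state.mh_log_step), rng)
        state.upsilon = res.new_upsilon
        state.mh_proposals += 1
        state.mh_accepted += int(res.accepted)
        if adapt_t is not None and spec.adapt_mh:
            state.mh_log_step += (float(res.accepted) - 0.44) / (adapt_t + 1) ** 0.6
    elif spec.family in ("bayesA", "bayesB"):
        pi = spec.pi if spec.family == "bayesB" else 0.0
        df = spec.df_ab
        K.sweep_markers_bayesAB(state.X, state.wx, state.resid, state.beta,
                                state.xwx, state.sigma2_beta_k, state.delta,
                                pi, df, state.s2_beta, state.sigma2_e, z,
                                rng.gamma(0.5 * (df + 1.0), size=m),
                                rng.gamma(0.5 * df, size=m),
                                rng.uniform(size=m))
    else:  # pragma: no cover
        raise ValueError(spec.family)
    update_residual_variance(state, rng)
    return state


def run_chain(g: GenotypeMatrix, ph: PhenotypeTable, spec: ModelSpec,
              cfg: ChainConfig, refresh_every: int = 1_000,
              save_beta: bool = False) -> PosteriorSummary:
    """Run one seeded Gibbs chain and summarize the saved draws.

    Saves every ``thin``-th post-burn-in draw of mu, the realized additive
    variance Vg = var(X beta), the residual variance, tau^2 and (bayesHE)
    upsilon; beta is averaged over the saved draws.  Deterministic given
    ``cfg.seed``.
    """
    state = init_state(g, ph, spec, cfg)
    rng = np.random.default_rng(cfg.seed)
    n_saved = cfg.n_saved
    mu_tr = np.empty(n_saved)
    vg_tr = np.empty(n_saved)
    s2e_tr = np.empty(n_saved)
    tau2_tr = np.empty(n_saved)
    ups_tr = np.empty(n_saved) if spec.family == "bayesHE" else None
    beta_sum = np.zeros(state.m)
    delta_sum = np.zeros(state.m) if spec.family == "bayesB" else None
    beta_tr = np.empty((n_saved, state.m)) if save_beta else None
    j = 0
    for it in range(1, cfg.n_iter + 1):
        adapt_t = it if (it <= cfg.burn_in and spec.family == "bayesHE") else None
        fast_sweep(state, rng, adapt_t=adapt_t)
        if refresh_every and it % refresh_every == 0:
            state.refresh_residuals()
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            if not (math.isfinite(state.mu) and math.isfinite(state.sigma2_e)
                    and np.isfinite(state.beta).all()):
                raise RuntimeError(f"divergent sampler state at iteration {it}")
            gv = state.X @ state.beta
            mu_tr[j] = state.mu
            vg_tr[j] = float(np.var(gv, ddof=1))
            s2e_tr[j] = state.sigma2_e
            tau2_tr[j] = state.tau2
            if ups_tr is not None:
                ups_tr[j] = state.upsilon
            beta_sum += state.beta
            if delta_sum is not None:
                delta_sum += state.delta
            if beta_tr is not None:
                beta_tr[j] = state.beta
            j += 1
    assert j == n_saved
    acc = (state.mh_accepted / state.mh_proposals
           if spec.family == "bayesHE" and state.mh_proposals else None)
    return PosteriorSummary(
        beta_mean=beta_sum / n_saved,
        mu_trace=mu_tr, vg_trace=vg_tr, sigma2e_trace=s2e_tr, tau2_trace=tau2_tr,
        upsilon_trace=ups_tr,
        mu_mean=float(mu_tr.mean()),
        sigma2_e_mean=float(s2e_tr.mean()),
        upsilon_mean=float(ups_tr.mean()) if ups_tr is not None else None,
        acceptance_rate=acc,
        n_saved=n_saved,
        delta_mean=None if delta_sum is None else delta_sum / n_saved,
        beta_trace=beta_tr,
        spec=spec, config=cfg,
        train_freqs=np.asarray(g.freqs, dtype=float).copy(),
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def genomic_values(g: GenotypeMatrix, beta: np.ndarray, mu: float = 0.0) -> np.ndarray:
    """Direct genomic values DGV_i = sum_k x_ik beta_k (intercept excluded).

    DGVs enter only correlation/regression metrics, which are invariant to
    the constant shift that column centering adds, so raw codes are used.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size != g.n_markers:
        raise ValueError(f"effect vector length {beta.size} != m = {g.n_markers}")
    return g.codes @ beta


def additive_variance(g: GenotypeMatrix, beta: np.ndarray) -> float:
    """Realized additive variance Vg = var(sum_k x_k beta_k), denominator n-1."""
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    return float(np.var(genomic_values(g, beta), ddof=1))
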