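"""Shared fixtures and numeric-oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from bayesgl import ChainConfig, GenotypeMatrix, ModelSpec, PhenotypeTable, init_state


def make_genotypes(n=12, m=6, seed=0, p_range=(0.2, 0.8)) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=m)
    codes = rng.binomial(2, p, size=(n, m)).astype(float)
    codes[0] = 0.0  # force both alleles present in every column
    codes[1] = 2.0
    return GenotypeMatrix([f"i{i}" for i in range(n)],
                          [f"m{j}" for j in range(m)], codes)


def make_state(family="bayesU", n=8, m=3, seed=0, **spec_kw):
    """A small valid sampler state with randomized latents."""
    g = make_genotypes(n, m, seed)
    rng = np.random.default_rng(seed + 1)
    y = rng.standard_normal(n) + g.codes[:, 0] * 0.5
    ph = PhenotypeTable(g.individual_ids, y,
                        reliability=rng.uniform(0.4, 0.9, n))
    st = init_state(g, ph, ModelSpec(family=family, **spec_kw), None)
    st.beta = rng.standard_normal(m) * 0.3
    st.refresh_residuals()
    st.lam2 = rng.uniform(0.3, 3.0, m)
    st.theta = rng.uniform(0.3, 3.0, m)
    st.eta2 = rng.uniform(0.3, 3.0, m)
    st.nu_aux = rng.uniform(0.3, 3.0, m)
    st.tau2 = 0.7
    st.xi = 1.3
    return st


@pytest.fixture
def tiny_g():
    return make_genotypes()


@pytest.fixture
def tiny_ph(tiny_g):
    rng = np.random.default_rng(42)
    return PhenotypeTable(tiny_g.individual_ids,
                          rng.standard_normal(tiny_g.n_individuals))


@pytest.fixture
def short_cfg():
    return ChainConfig(n_iter=400, burn_in=200, thin=10, seed=7)


# ---------------------------------------------------------------------------
# grid-integration oracle
# ---------------------------------------------------------------------------

def grid_cdf(logpdf, x_lo: float, x_hi: float, n_grid: int = 40_001):
    """Normalized CDF of an unnormalized density on (x_lo, x_hi), computed
    by trapezoid integration in u = log(x) (positive support assumed)."""
    u = np.linspace(np.log(x_lo), np.log(x_hi), n_grid)
    x = np.exp(u)
    logp = logpdf(x) + u  # Jacobian of x = exp(u)
    p = np.exp(logp - logp.max())
    du = u[1] - u[0]
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * du)])
    return x, cdf / cdf[-1]


def sup_cdf_gap(logpdf, claimed_dist, tail: float = 1e-9) -> float:
    """Max |grid-integrated CDF - claimed scipy distribution CDF|.

    The integration window is taken from the claimed distribution's
    extreme quantiles; if the claim is wrong the mismatch shows up as a
    large gap.
    """
    x_lo = claimed_dist.ppf(tail)
    x_hi = claimed_dist.ppf(1.0 - tail)
    x, cdf = grid_cdf(logpdf, x_lo, x_hi)
    return float(np.max(np.abs(cdf - (claimed_dist.cdf(x) - claimed_dist.cdf(x_lo))
                               / (claimed_dist.cdf(x_hi) - claimed_dist.cdf(x_lo)))))


def batch_se(x: np.ndarray, n_batches: int = 40) -> float:
    """Batch-means standard error for an autocorrelated scalar chain."""
    x = np.asarray(x, dtype=float)
    b = max(len(x) // n_batches, 1)
    nb = len(x) // b
    means = x[: nb * b].reshape(nb, b).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))
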