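"""Global-local hierarchy conditionals: grid-integration oracles, the
half-Cauchy mixture identity, and the Metropolis-Hastings df step."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from bayesgl import gl_priors
from bayesgl._kernels import LAM2_MAX, LAM2_MIN
from bayesgl.gl_priors import (
    DFSampleResult,
    log_conditional_df,
    sample_df_mh,
    update_global_bayesU,
    update_global_halfcauchy,
    update_locals_bayesHE,
    update_locals_bayesHP,
    update_locals_bayesU,
)

from conftest import batch_se, make_state, sup_cdf_gap

N_KS = 100_000


def ig_logpdf(x, shape, rate):
    return -(shape + 1.0) * np.log(x) - rate / x


def invgamma(shape, rate):
    return stats.invgamma(shape, scale=rate)


def chain_ig_draws(rng, size, *layers):
    """Compose chained IG draws: each layer maps the previous draw to a
    (shape, rate) pair."""
    x = None
    for layer in layers:
        shape, rate = layer(x)
        x = rate / rng.gamma(shape, size=size)
    return x


class TestMixtureIdentity:
    """If x^2 ~ IG(1/2, 1/a) and a ~ IG(1/2, 1/A^2) then x ~ C+(0, A)."""

    @pytest.mark.parametrize("A", [1.0, 1.0 / 500.0])
    def test_half_cauchy_reconstruction(self, A):
        rng = np.random.default_rng(17)
        x2 = chain_ig_draws(rng, N_KS,
                            lambda _: (0.5, 1.0 / A**2),
                            lambda a: (0.5, 1.0 / a))
        d, _ = stats.kstest(np.sqrt(x2), stats.halfcauchy(scale=A).cdf)
        assert d < 0.01


class TestBayesULocals:
    def test_lambda2_conditional_matches_grid_oracle(self):
        st = make_state("bayesU", seed=21)
        k = 1
        b2, t2, nu = st.beta[k] ** 2, st.tau2, st.nu_aux[k]
        claimed = invgamma(1.0, 1.0 / nu + b2 / (2 * t2))

        def log_post(l2):
            return (ig_logpdf(l2, 0.5, 1.0 / nu)
                    - 0.5 * np.log(l2) - b2 / (2 * l2 * t2))

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_zero_effect_keeps_half_unit_shape_increment(self):
        # at beta_k = 0 the Gaussian normalizer still contributes a
        # (lam^2)^(-1/2) factor: conditional is IG(1, 1/nu), zero rate added
        nu = 0.8
        claimed = invgamma(1.0, 1.0 / nu)

        def log_post(l2):
            return ig_logpdf(l2, 0.5, 1.0 / nu) - 0.5 * np.log(l2)

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_sampler_follows_derived_conditional(self):
        st = make_state("bayesU", seed=22)
        k = 0
        rng = np.random.default_rng(5)
        draws = np.empty(N_KS)
        lam2_0, nu_0 = st.lam2[k], st.nu_aux[k]
        for i in range(N_KS):
            st.lam2[k], st.nu_aux[k] = lam2_0, nu_0
            update_locals_bayesU(st, k, rng)
            draws[i] = st.lam2[k]
        claimed = invgamma(1.0, 1.0 / nu_0 + st.beta[k] ** 2 / (2 * st.tau2))
        d, _ = stats.kstest(draws, claimed.cdf)
        assert d < 0.01

    def test_marginal_local_scale_is_half_cauchy(self):
        # nu ~ IG(1/2, 1), lam2 | nu ~ IG(1/2, 1/nu) => lam ~ C+(0, 1)
        rng = np.random.default_rng(23)
        lam2 = chain_ig_draws(rng, N_KS,
                              lambda _: (0.5, 1.0),
                              lambda nu: (0.5, 1.0 / nu))
        d, _ = stats.kstest(np.sqrt(lam2), stats.halfcauchy.cdf)
        assert d < 0.01


class TestBayesUGlobal:
    def test_flat_tau_conditional_matches_grid_oracle(self):
        st = make_state("bayesU", m=4, seed=24)
        S = float(np.sum(st.beta**2 / st.lam2))
        m = st.m
        claimed = invgamma(0.5 * (m - 1.0), 0.5 * S)

        def log_post(t2):
            # flat prior on tau => (tau^2)^(-1/2) transform factor
            return -0.5 * np.log(t2) - 0.5 * m * np.log(t2) - 0.5 * S / t2

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_effect_scaling_quadruples_rate(self):
        st = make_state("bayesU", m=4, seed=25)
        S1 = float(np.sum(st.beta**2 / st.lam2))
        st.beta *= 2.0
        S2 = float(np.sum(st.beta**2 / st.lam2))
        assert S2 == pytest.approx(4.0 * S1)

    def test_single_marker_improper(self):
        st = make_state("bayesU", m=1, seed=26)
        with pytest.raises(ValueError, match="improper"):
            update_global_bayesU(st, np.random.default_rng(0))

    def test_vanishing_effects_hit_floor_not_zero(self):
        st = make_state("bayesU", m=3, seed=27)
        st.beta = np.zeros(st.m)
        update_global_bayesU(st, np.random.default_rng(1))
        assert st.tau2 >= LAM2_MIN


class TestBayesHPConditionals:
    @pytest.fixture
    def st(self):
        return make_state("bayesHP", seed=28)

    def test_lambda2_grid_oracle(self, st):
        k = 0
        b2, t2, th = st.beta[k] ** 2, st.tau2, st.theta[k]
        claimed = invgamma(1.0, 1.0 / th + b2 / (2 * t2))

        def log_post(l2):
            return ig_logpdf(l2, 0.5, 1.0 / th) - 0.5 * np.log(l2) - b2 / (2 * l2 * t2)

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_theta_grid_oracle(self, st):
        k = 1
        l2, e2 = st.lam2[k], st.eta2[k]
        claimed = invgamma(1.0, 1.0 / e2 + 1.0 / l2)

        def log_post(th):
            # prior IG(1/2, 1/eta2) times IG likelihood of lam2 given theta
            return (ig_logpdf(th, 0.5, 1.0 / e2)
                    - 0.5 * np.log(th) - 1.0 / (th * l2))

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_eta2_grid_oracle(self, st):
        k = 2
        th, nu = st.theta[k], st.nu_aux[k]
        claimed = invgamma(1.0, 1.0 / nu + 1.0 / th)

        def log_post(e2):
            return (ig_logpdf(e2, 0.5, 1.0 / nu)
                    - 0.5 * np.log(e2) - 1.0 / (e2 * th))

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_nu_grid_oracle(self, st):
        k = 0
        e2 = st.eta2[k]
        claimed = invgamma(1.0, 1.0 + 1.0 / e2)

        def log_post(nu):
            return ig_logpdf(nu, 0.5, 1.0) - 0.5 * np.log(nu) - 1.0 / (nu * e2)

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_composed_prior_matches_horseshoe_plus_density(self):
        """The chained IG layers reproduce lam ~ C+(0, eta), eta ~ C+(0,1),
        whose marginal density is (4/pi^2) log(lam)/(lam^2 - 1)."""
        rng = np.random.default_rng(29)
        lam2 = chain_ig_draws(rng, N_KS,
                              lambda _: (0.5, 1.0),            # nu
                              lambda nu: (0.5, 1.0 / nu),      # eta^2
                              lambda e2: (0.5, 1.0 / e2),      # theta
                              lambda th: (0.5, 1.0 / th))      # lam^2
        lam = np.sqrt(lam2)

        grid = np.concatenate([np.linspace(1e-6, 0.999, 4000),
                               np.geomspace(1.001, 1e7, 8000)])
        dens = 4.0 / math.pi**2 * np.log(grid) / (grid**2 - 1.0)
        cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(lam), grid) / lam.size
        assert np.max(np.abs(emp - cdf)) < 0.01


class TestGlobalHalfCauchy:
    def test_tau2_grid_oracle(self):
        st = make_state("bayesHP", m=4, seed=30)
        S = float(np.sum(st.beta**2 / st.lam2))
        m, xi = st.m, st.xi
        claimed = invgamma(0.5 * (m + 1.0), 1.0 / xi + 0.5 * S)

        def log_post(t2):
            return (ig_logpdf(t2, 0.5, 1.0 / xi)
                    - 0.5 * m * np.log(t2) - 0.5 * S / t2)

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_xi_conditional_scales_with_N_squared(self):
        # huge effects force tau^2 >> 1, so xi | tau^2 ~ IG(1, N^2) and the
        # prior rate term N^2 dominates; compare medians across N
        st = make_state("bayesHP", m=3, seed=31)
        st.beta = np.full(st.m, 1e6)
        st.lam2 = np.ones(st.m)
        rng = np.random.default_rng(6)
        meds = {}
        for N in (100, 200):
            st.N = N
            draws = []
            for _ in range(4000):
                update_global_halfcauchy(st, rng)
                draws.append(st.xi)
            meds[N] = np.median(draws)
        assert meds[200] / meds[100] == pytest.approx(4.0, rel=0.15)

    def test_composed_global_prior_is_half_cauchy_1_over_N(self):
        N = 500
        rng = np.random.default_rng(32)
        tau2 = chain_ig_draws(rng, N_KS,
                              lambda _: (0.5, float(N) ** 2),
                              lambda xi: (0.5, 1.0 / xi))
        d, _ = stats.kstest(np.sqrt(tau2), stats.halfcauchy(scale=1.0 / N).cdf)
        assert d < 0.01


class TestBayesHELocals:
    @pytest.mark.parametrize("ups", [1.0, 4.0, 30.0])
    def test_lambda2_grid_oracle_across_df(self, ups):
        st = make_state("bayesHE", seed=33)
        st.upsilon = ups
        k = 0
        b2, t2, th = st.beta[k] ** 2, st.tau2, st.theta[k]
        claimed = invgamma(0.5 * (ups + 1.0), ups / th + b2 / (2 * t2))

        def log_post(l2):
            return (ig_logpdf(l2, 0.5 * ups, ups / th)
                    - 0.5 * np.log(l2) - b2 / (2 * l2 * t2))

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    @pytest.mark.parametrize("ups", [1.0, 4.0, 30.0])
    def test_theta_grid_oracle_across_df(self, ups):
        st = make_state("bayesHE", seed=34)
        st.upsilon = ups
        k = 1
        l2 = st.lam2[k]
        claimed = invgamma(0.5 * (1.0 + ups), 1.0 + ups / l2)

        def log_post(th):
            # prior IG(1/2, 1) times the (ups/theta)^(ups/2) exp(-ups/(theta lam2))
            # part of the lam2 likelihood
            return (ig_logpdf(th, 0.5, 1.0)
                    - 0.5 * ups * np.log(th) - ups / (th * l2))

        assert sup_cdf_gap(log_post, claimed) < 1e-3

    def test_df_one_reduces_to_horseshoe_local(self):
        # upsilon = 1: lam2 ~ IG(1/2, 1/theta), theta ~ IG(1/2, 1) => lam ~ C+(0,1)
        rng = np.random.default_rng(35)
        lam2 = chain_ig_draws(rng, N_KS,
                              lambda _: (0.5, 1.0),
                              lambda th: (0.5, 1.0 / th))
        d, _ = stats.kstest(np.sqrt(lam2), stats.halfcauchy.cdf)
        assert d < 0.015

    def test_large_df_concentrates_local_scale(self):
        rng = np.random.default_rng(36)
        spreads = []
        for ups in (4.0, 16.0, 64.0):
            lam2 = (ups / 1.0) / rng.gamma(0.5 * ups, size=20_000)  # theta = 1
            spreads.append(np.var(lam2))
        assert spreads[0] > spreads[1] > spreads[2]

    def test_update_respects_clamp_bounds(self):
        st = make_state("bayesHE", seed=37)
        st.upsilon = 0.05
        rng = np.random.default_rng(7)
        for k in range(st.m):
            for _ in range(50):
                update_locals_bayesHE(st, k, rng)
                assert LAM2_MIN <= st.lam2[k] <= LAM2_MAX


class TestLogConditionalDF:
    def test_no_data_reduces_to_gamma_kernel(self):
        a, b = 4.0, 1.0
        for ups in (0.3, 1.0, 4.0, 27.0):
            got = log_conditional_df(ups, np.empty(0), np.empty(0), a, b)
            assert got == pytest.approx((a - 1.0) * math.log(ups) - b * ups)

    def test_unit_scales_direct_evaluation(self):
        # m=1, theta = lam2 = 1: log-sum term 0, reciprocal term 1
        a, b, ups = 4.0, 1.0, 2.5
        expected = ((ups * 0.5 + a - 1.0) * math.log(ups)
                    - gammaln(ups / 2.0) - ups * (0.0 + 1.0 + b))
        got = log_conditional_df(ups, np.ones(1), np.ones(1), a, b)
        assert got == pytest.approx(expected)

    def test_finite_over_wide_support(self):
        rng = np.random.default_rng(38)
        theta = rng.uniform(0.2, 3.0, 20)
        lam2 = rng.uniform(0.2, 3.0, 20)
        for ups in (1e-3, 1.0, 1e3):
            assert math.isfinite(log_conditional_df(ups, theta, lam2, 4.0, 1.0))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            log_conditional_df(-1.0, np.ones(2), np.ones(2), 4.0, 1.0)
        with pytest.raises(ValueError):
            log_conditional_df(1.0, np.array([np.nan, 1.0]), np.ones(2), 4.0, 1.0)


class _DFState:
    """Minimal state for isolated Metropolis-Hastings runs."""

    def __init__(self, upsilon, theta, lam2):
        self.upsilon = upsilon
        self.theta = np.asarray(theta, dtype=float)
        self.lam2 = np.asarray(lam2, dtype=float)
        self.m = self.theta.size


def run_mh(state, a, b, step, n_iter, rng, warm=2_000):
    out = np.empty(n_iter)
    acc = 0
    for i in range(warm + n_iter):
        res = sample_df_mh(state, a, b, step, rng)
        state.upsilon = res.new_upsilon
        if i >= warm:
            out[i - warm] = state.upsilon
            acc += int(res.accepted)
    return out, acc / n_iter


class TestSampleDFMH:
    def test_tiny_step_accepts_everything(self):
        st = _DFState(4.0, np.ones(5), np.ones(5))
        _, acc = run_mh(st, 4.0, 1.0, 1e-7, 2_000, np.random.default_rng(8),
                        warm=0)
        assert acc > 0.999

    @pytest.mark.parametrize("a,prior_mean", [(4.0, 4.0), (5.0, 5.0)])
    def test_prior_recovery_without_data(self, a, prior_mean):
        """m = 0: the chain must recover the Gamma(a, 1) prior for upsilon."""
        st = _DFState(1.0, np.empty(0), np.empty(0))
        draws, _ = run_mh(st, a, 1.0, 0.8, 60_000, np.random.default_rng(9))
        assert abs(draws.mean() - prior_mean) < 3 * batch_se(draws)

    def test_posterior_mean_matches_quadrature_oracle(self):
        """m = 50 frozen state simulated at upsilon_true = 6."""
        rng = np.random.default_rng(10)
        m, ups_true, a, b = 50, 6.0, 4.0, 1.0
        theta = 1.0 / rng.gamma(0.5, size=m)                 # IG(1/2, 1)
        lam2 = (ups_true / theta) / rng.gamma(0.5 * ups_true, size=m)
        grid = np.linspace(1e-3, 100.0, 200_001)
        logk = np.array([log_conditional_df(u, theta, lam2, a, b) for u in
                         grid[:: 100]])
        # refine on the evaluated subgrid (kernel is smooth)
        sub = grid[::100]
        w = np.exp(logk - logk.max())
        oracle_mean = float(np.trapezoid(sub * w, sub) / np.trapezoid(w, sub))
        st = _DFState(a / b, theta, lam2)
        draws, acc = run_mh(st, a, b, 0.5, 60_000, np.random.default_rng(11))
        assert 0.1 < acc < 0.9
        assert abs(draws.mean() - oracle_mean) < 3 * batch_se(draws)

    def test_rejection_keeps_state(self):
        st = _DFState(4.0, np.ones(3), np.ones(3))
        rng = np.random.default_rng(12)
        for _ in range(200):
            res = sample_df_mh(st, 4.0, 1.0, 5.0, rng)
            if not res.accepted:
                assert res.new_upsilon == st.upsilon
            st.upsilon = res.new_upsilon

    def test_result_type_validates_positivity(self):
        with pytest.raises(ValueError):
            DFSampleResult(-1.0, True, 0.0)

    def test_detailed_balance_between_bins(self):
        """Empirical probability flow between two upsilon bins balances."""
        st = _DFState(4.0, np.ones(4), np.ones(4))
        rng = np.random.default_rng(13)
        prev_bin, flows = None, {"ab": 0, "ba": 0}
        for i in range(120_000):
            res = sample_df_mh(st, 4.0, 1.0, 0.8, rng)
            st.upsilon = res.new_upsilon
            cur_bin = "a" if st.upsilon < 3.0 else "b"
            if i > 2_000 and prev_bin is not None:
                if prev_bin == "a" and cur_bin == "b":
                    flows["ab"] += 1
                elif prev_bin == "b" and cur_bin == "a":
                    flows["ba"] += 1
            prev_bin = cur_bin
        diff = abs(flows["ab"] - flows["ba"])
        assert diff < 4 * math.sqrt(flows["ab"] + flows["ba"])


class TestShrinkageMonotonicity:
    def test_conditional_mean_effect_magnitude_grows_with_prior_variance(self):
        from bayesgl._kernels import beta_params

        st = make_state("bayesU", n=10, m=2, seed=39)
        k = 0
        s = float(st.wx[:, k] @ st.resid) + st.xwx[k] * st.beta[k]
        means = []
        for pv in np.geomspace(1e-6, 1e4, 30):
            mean, sd = beta_params(s, st.xwx[k], pv, st.sigma2_e)
            # folded-normal mean of |beta_k|
            means.append(sd * math.sqrt(2 / math.pi)
                         * math.exp(-0.5 * (mean / sd) ** 2)
                         + abs(mean) * math.erf(abs(mean) / (sd * math.sqrt(2))))
        assert np.all(np.diff(means) >= -1e-12)
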