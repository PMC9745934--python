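import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, gammaln
from scipy.stats import betabinom

from metafew import (
    MetaDataset,
    StudyRecord,
    betabin_logpmf,
    fit_bbcb1,
    fit_bbcb2,
    fit_bbfr,
    fit_bbst,
    t_confidence_interval,
)
from metafew.betabin import (
    BetaBinomialCommonBetaArms,
    BetaBinomialCommonRho,
    BetaBinomialRandomEffect,
    _alpha_beta,
)
from conftest import swap_arms


def nine_log_gamma(y, n, alpha, beta):
    """Arm-level log likelihood written out in its nine log-gamma terms."""
    return (
        gammaln(n + 1)
        + gammaln(y + alpha)
        + gammaln(n - y + beta)
        + gammaln(alpha + beta)
        - gammaln(y + 1)
        - gammaln(n - y + 1)
        - gammaln(n + alpha + beta)
        - gammaln(alpha)
        - gammaln(beta)
    )


class TestLogPmf:
    @pytest.mark.parametrize(
        "y, n, a, b, expected",
        [
            (1, 1, 2.0, 3.0, math.log(0.4)),  # single trial: P = mu = a/(a+b)
            (0, 2, 2.0, 3.0, math.log(0.4)),
            (1, 2, 2.0, 3.0, math.log(0.4)),
            (2, 2, 2.0, 3.0, math.log(0.2)),
        ],
    )
    def test_closed_form_values(self, y, n, a, b, expected):
        assert betabin_logpmf(y, n, a, b) == pytest.approx(expected, abs=1e-12)

    def test_uniform_case(self):
        # Beta(1,1) mixing gives the discrete uniform on 0..n
        for y in range(6):
            assert betabin_logpmf(y, 5, 1.0, 1.0) == pytest.approx(math.log(1 / 6), abs=1e-12)

    @given(
        n=st.integers(1, 50),
        a=st.floats(0.05, 50.0),
        b=st.floats(0.05, 50.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_normalizes_and_matches_nine_log_gamma(self, n, a, b):
        y = np.arange(n + 1)
        lp = betabin_logpmf(y, n, a, b)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(lp, nine_log_gamma(y, n, a, b), atol=1e-10)

    @given(n=st.integers(1, 40), a=st.floats(0.1, 20.0), b=st.floats(0.1, 20.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_scipy_betabinom(self, n, a, b):
        y = np.arange(n + 1)
        np.testing.assert_allclose(
            betabin_logpmf(y, n, a, b), betabinom.logpmf(y, n, a, b), atol=1e-10
        )


class TestTInterval:
    def test_df4(self):
        lo, hi = t_confidence_interval(0.0, 1.0, 4)
        assert (lo, hi) == (pytest.approx(-2.776, abs=1e-3), pytest.approx(2.776, abs=1e-3))

    def test_df1(self):
        lo, hi = t_confidence_interval(0.0, 1.0, 1)
        assert hi == pytest.approx(12.706, abs=1e-3)

    def test_zero_se_degenerate(self):
        assert t_confidence_interval(1.5, 0.0, 3) == (1.5, 1.5)

    def test_bad_df(self):
        with pytest.raises(ValueError):
            t_confidence_interval(0.0, 1.0, 0)

    def test_k_minus_1_never_shorter_than_2k_minus_2(self, k3):
        narrow = fit_bbst(k3, df_rule="2k-2")
        wide = fit_bbst(k3, df_rule="k-1")
        assert (wide.ci_hi - wide.ci_lo) >= (narrow.ci_hi - narrow.ci_lo)


class TestCommonRho:
    def test_negloglik_equals_per_arm_summation(self, k3):
        est = BetaBinomialCommonRho()
        params = np.array([-1.2, 0.4, -2.0])
        rho = expit(-2.0)
        a_c, b_c = _alpha_beta(expit(-1.2), rho)
        a_t, b_t = _alpha_beta(expit(-0.8), rho)
        naive = 0.0
        for s in k3.studies:
            naive += betabin_logpmf(s.y_c, s.n_c, a_c, b_c)
            naive += betabin_logpmf(s.y_t, s.n_t, a_t, b_t)
        assert est.negloglik(params, k3) == pytest.approx(-naive, abs=1e-10)

    def test_rho_to_zero_recovers_binomial_loglik(self, k3):
        from scipy.stats import binom

        est = BetaBinomialCommonRho()
        # rho = expit(-18) ~ 1.5e-8: small enough that the beta-binomial is
        # within ~1e-5 of the binomial, large enough to avoid log-gamma
        # cancellation noise
        val = est.negloglik(np.array([-1.2, 0.4, -18.0]), k3)
        naive = 0.0
        for s in k3.studies:
            naive += binom.logpmf(s.y_c, s.n_c, expit(-1.2))
            naive += binom.logpmf(s.y_t, s.n_t, expit(-0.8))
        assert val == pytest.approx(-naive, abs=1e-3)

    def test_symmetric_data_gives_null_effect(self):
        ds = MetaDataset(
            [StudyRecord("1", 4, 10, 4, 10), StudyRecord("2", 6, 15, 6, 15)]
        )
        res = fit_bbst(ds)
        assert res.converged
        assert res.est == pytest.approx(0.0, abs=1e-4)

    def test_matches_grid_search_oracle(self):
        """Refined dense grid over (b0, b_t, logit rho) as an independent
        maximum-likelihood oracle, on overdispersed data where the optimum
        is interior (rho well away from zero)."""
        ds = MetaDataset.from_counts([[30, 100, 5, 100], [10, 100, 25, 100]])
        est = BetaBinomialCommonRho().fit(ds)
        assert est.converged_

        b0s = np.linspace(-4, 0, 21)
        bts = np.linspace(-1, 2, 21)
        lrs = np.linspace(-6, 2, 17)
        for _ in range(4):
            vals = np.empty((len(b0s), len(bts), len(lrs)))
            for i, b0 in enumerate(b0s):
                for j, bt in enumerate(bts):
                    for l, lr in enumerate(lrs):
                        vals[i, j, l] = est.negloglik(np.array([b0, bt, lr]), ds)
            i, j, l = np.unravel_index(np.argmin(vals), vals.shape)
            best = (b0s[i], bts[j], lrs[l])
            w = b0s[1] - b0s[0], bts[1] - bts[0], lrs[1] - lrs[0]
            b0s = np.linspace(best[0] - w[0], best[0] + w[0], 9)
            bts = np.linspace(best[1] - w[1], best[1] + w[1], 9)
            lrs = np.linspace(best[2] - w[2], best[2] + w[2], 9)
        assert est.effect_ == pytest.approx(best[1], abs=1e-3)

    def test_study_order_invariance(self, k3):
        shuffled = MetaDataset([k3.studies[2], k3.studies[0], k3.studies[1]])
        a = fit_bbst(k3)
        b = fit_bbst(shuffled)
        assert a.est == pytest.approx(b.est, abs=1e-7)

    def test_arm_swap_negates_effect(self, k3):
        a = fit_bbst(k3)
        b = fit_bbst(swap_arms(k3))
        assert a.est == pytest.approx(-b.est, abs=1e-4)

    def test_all_zero_arm_group_inestimable(self):
        ds = MetaDataset([StudyRecord("1", 0, 10, 3, 10), StudyRecord("2", 0, 12, 2, 12)])
        res = fit_bbst(ds)
        assert not res.converged

    def test_parameter_recovery(self, recovery_bbst):
        # generated from the model itself at b_t = -0.5
        res = fit_bbst(recovery_bbst)
        assert res.converged
        assert res.est == pytest.approx(-0.5, abs=0.05)

    def test_common_rho_constraint_alpha_beta_sums(self, k2):
        est = BetaBinomialCommonRho().fit(k2)
        b0, bt, lrho = est.params_
        rho = expit(lrho)
        a_c, b_c = _alpha_beta(expit(b0), rho)
        a_t, b_t = _alpha_beta(expit(b0 + bt), rho)
        assert a_c + b_c == pytest.approx(a_t + b_t, rel=1e-12)


class TestRandomEffectExtension:
    def test_homogeneous_data_matches_common_rho(self):
        ds = MetaDataset(
            [
                StudyRecord("1", 30, 200, 20, 200),
                StudyRecord("2", 28, 200, 21, 200),
                StudyRecord("3", 31, 200, 19, 200),
            ]
        )
        plain = fit_bbst(ds)
        extended = fit_bbfr(ds)
        assert extended.converged
        assert extended.est == pytest.approx(plain.est, abs=1e-2)

    def test_quadrature_matches_dense_integration(self):
        from scipy import integrate

        est = BetaBinomialRandomEffect(quad_points=30)
        eta = np.array([-1.5])
        y, n = np.array([12.0]), np.array([60.0])
        rho, s2 = 0.05, 0.4
        agq = est._marginal_treat_ll(eta, rho, s2, y, n, "logit", 30)[0]

        def integrand(g):
            ll = est._bb_treat_parts(np.array([g]), eta, rho, y, n, "logit")[0][0]
            return math.exp(ll - g * g / (2 * s2)) / math.sqrt(2 * math.pi * s2)

        dense, _ = integrate.quad(integrand, -8, 8, limit=200)
        assert agq == pytest.approx(math.log(dense), abs=1e-4)

    def test_sigma2_estimated_near_zero_without_heterogeneity(self):
        ds = MetaDataset(
            [
                StudyRecord("1", 30, 200, 20, 200),
                StudyRecord("2", 28, 200, 21, 200),
                StudyRecord("3", 31, 200, 19, 200),
            ]
        )
        est = BetaBinomialRandomEffect().fit(ds)
        assert est.converged_
        assert est.sigma2_ < 1e-2


class TestCommonBeta:
    def test_symmetric_data_null_effect(self):
        ds = MetaDataset(
            [StudyRecord("1", 4, 10, 4, 10), StudyRecord("2", 6, 15, 6, 15)]
        )
        res = fit_bbcb1(ds)
        assert res.converged
        assert res.est == pytest.approx(0.0, abs=1e-4)

    def test_matches_grid_search_oracle(self):
        """Dense refined grid over (logit mu_C, logit mu_T, log beta) on
        overdispersed data with an interior optimum."""
        k2 = MetaDataset.from_counts([[30, 100, 5, 100], [10, 100, 25, 100]])
        est = BetaBinomialCommonBetaArms().fit(k2)
        assert est.converged_
        x1s = np.linspace(-4, 0, 17)
        x2s = np.linspace(-3, 1, 17)
        x3s = np.linspace(0, 6, 17)
        best = None
        for _ in range(5):
            vals = np.empty((len(x1s), len(x2s), len(x3s)))
            for i, x1 in enumerate(x1s):
                for j, x2 in enumerate(x2s):
                    for l, x3 in enumerate(x3s):
                        vals[i, j, l] = est.negloglik(np.array([x1, x2, x3]), k2)
            i, j, l = np.unravel_index(np.argmin(vals), vals.shape)
            best = (x1s[i], x2s[j], x3s[l])
            w = x1s[1] - x1s[0], x2s[1] - x2s[0], x3s[1] - x3s[0]
            x1s = np.linspace(best[0] - w[0], best[0] + w[0], 9)
            x2s = np.linspace(best[1] - w[1], best[1] + w[1], 9)
            x3s = np.linspace(best[2] - w[2], best[2] + w[2], 9)
        assert est.effect_ == pytest.approx(best[1] - best[0], abs=3e-3)

    def test_conditional_pmf_normalizes(self):
        # P(y_T | m) over y_T = 0..m sums to one for fixed parameters
        b0, bt = -2.0, 0.7
        n_t, n_c, m = 40, 50, 12
        lam_t, lam_c = n_t * math.exp(b0 + bt), n_c * math.exp(b0)
        total = sum(math.exp(betabin_logpmf(y, m, lam_t, lam_c)) for y in range(m + 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_conditional_symmetric_counts_null_effect(self):
        ds = MetaDataset(
            [StudyRecord("1", 5, 20, 5, 20), StudyRecord("2", 3, 30, 3, 30)]
        )
        res = fit_bbcb2(ds)
        assert res.converged
        assert res.est == pytest.approx(0.0, abs=1e-4)

    def test_conditional_all_empty_inestimable(self):
        ds = MetaDataset([StudyRecord("1", 0, 10, 0, 10)])
        res = fit_bbcb2(ds)
        assert not res.converged
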