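"""Beta-binomial models for meta-analysis of two-arm binary studies.

Four maximum-likelihood models are implemented:

``BetaBinomialCommonRho`` (BBST)
    Event counts in each arm group follow a beta-binomial distribution whose
    intraclass correlation rho = 1/(alpha + beta + 1) is shared between the
    treatment and control arm groups (equivalently alpha_C + beta_C =
    alpha_T + beta_T).  The treatment effect b_T is the contrast of the two
    group means on the link scale (logit for the odds ratio, log for the
    relative risk).  The treatment effect is fixed across studies; only the
    arm-level event probabilities are random.

``BetaBinomialRandomEffect`` (BBFR)
    The common-rho model extended with a per-study normal random deviation
    gamma_k ~ N(0, sigma2) added to the treatment effect, so the model
    respects the pairing of arms within a study.  The treatment-arm
    likelihood is marginalised over gamma_k by adaptive Gauss-Hermite
    quadrature; one node is the Laplace approximation and the working
    default.

``BetaBinomialCommonBetaArms`` (BBCB1)
    Common-beta model pooling arms across studies: y_ki ~ BetaBin(n_ki;
    alpha_i, beta) with arm-group-specific alpha_C, alpha_T and one shared
    beta.  On the logit scale the effect reduces to b_T = log(alpha_T) -
    log(alpha_C).  Odds ratio only.

``BetaBinomialCommonBetaConditional`` (BBCB2)
    Common-beta model conditioning on each study's total event count m_k:
    y_kT | m_k ~ BetaBin(m_k; n_kT exp(b0 + b_T), n_kC exp(b0)), the two-arm
    reduction of the fixed-effects negative-binomial panel likelihood with
    arm-size exposure offsets.  Odds ratio only.

Confidence intervals use the t distribution with K - 1 or 2K - 2 degrees
of freedom (the latter is the better-performing default).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize
from scipy.special import betaln, digamma, expit, gammaln, logit, logsumexp, polygamma

from ._numutils import (
    covariance_with_active_bounds,
    numeric_hessian,
    t_confidence_interval,
)
from .base import MetaAnalysisEstimator
from .data import Measure, MetaDataset, MethodResult

__all__ = [
    "betabin_logpmf",
    "t_confidence_interval",
    "BetaBinomialCommonRho",
    "BetaBinomialRandomEffect",
    "BetaBinomialCommonBetaArms",
    "BetaBinomialCommonBetaConditional",
    "fit_bbst",
    "fit_bbfr",
    "fit_bbcb1",
    "fit_bbcb2",
]

_PENALTY = 1e12
_MAX_EXP = 700.0


def betabin_logpmf(y, n, alpha, beta):
    """Log pmf of the beta-binomial distribution.

    ``log[ C(n, y) * B(y + alpha, n - y + beta) / B(alpha, beta) ]``, equal
    to the nine-log-gamma closed form of the arm-level likelihood
    contribution.  Vectorised over all arguments.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1.0)
        - gammaln(y + 1.0)
        - gammaln(n - y + 1.0)
        + betaln(y + alpha, n - y + beta)
        - betaln(alpha, beta)
    )


def _mean_from_link(eta, link: str):
    """Inverse link; returns (mu, valid) with mu possibly out of (0,1) flagged."""
    if link == "logit":
        mu = expit(eta)
        return mu, True
    # log link: mu = exp(eta) must stay below 1
    if eta >= 0.0:
        return None, False
    return math.exp(eta), True


def _link(measure: Measure) -> str:
    return "logit" if measure == Measure.OR else "log"


def _alpha_beta(mu: float, rho: float) -> tuple[float, float]:
    f = (1.0 - rho) / rho
    return mu * f, (1.0 - mu) * f


def _ml_minimize(negll, x0, bounds=None, polish=True):
    """Quasi-Newton fit, optionally polished by a bounded simplex search.

    The polish costs little for the closed-form likelihoods and removes the
    last ~1e-3 of optimizer slack that a quasi-Newton stop leaves behind.
    """
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
    )
    best = res
    if polish or (not res.success) or not np.isfinite(res.fun):
        start = res.x if np.isfinite(res.fun) else x0
        res2 = optimize.minimize(
            negll,
            start,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 400, "xatol": 1e-7, "fatol": 1e-11},
        )
        if np.isfinite(res2.fun) and (not np.isfinite(best.fun) or res2.fun < best.fun):
            best = res2
    return best


class BetaBinomialCommonRho(MetaAnalysisEstimator):
    """Common-rho beta-binomial meta-analysis model (BBST)."""

    method_name = "bbst"

    def __init__(self, measure: str = "or", df_rule: str = "2k-2", rho_start: float = 0.1):
        self.measure = measure
        self.df_rule = df_rule
        self.rho_start = rho_start

    def negloglik(self, params, dataset: MetaDataset) -> float:
        """Negative joint log likelihood at (b0, b_t, logit rho)."""
        b0, bt, lrho = params
        if abs(lrho) > 30 or abs(b0) > _MAX_EXP or abs(bt) > _MAX_EXP:
            return _PENALTY
        rho = expit(lrho)
        link = _link(self.measure_)
        mu_c, ok_c = _mean_from_link(b0, link)
        mu_t, ok_t = _mean_from_link(b0 + bt, link)
        if not (ok_c and ok_t) or not (0.0 < mu_c < 1.0 and 0.0 < mu_t < 1.0):
            return _PENALTY
        a_c, b_c = _alpha_beta(mu_c, rho)
        a_t, b_t_ = _alpha_beta(mu_t, rho)
        c = dataset.counts()
        ll = betabin_logpmf(c[:, 2], c[:, 3], a_c, b_c).sum()
        ll += betabin_logpmf(c[:, 0], c[:, 1], a_t, b_t_).sum()
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    def _start(self, dataset: MetaDataset, link: str):
        c = dataset.counts()
        p_t = (c[:, 0].sum() + 0.5) / (c[:, 1].sum() + 1.0)
        p_c = (c[:, 2].sum() + 0.5) / (c[:, 3].sum() + 1.0)
        g = logit if link == "logit" else np.log
        return np.array([g(p_c), g(p_t) - g(p_c), logit(self.rho_start)])

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        self.n_studies_used_ = dataset.k
        c = dataset.counts()
        # OR/RR inestimable when one arm group has no events at all
        if c[:, 0].sum() == 0 or c[:, 2].sum() == 0:
            return self
        negll = lambda p: self.negloglik(p, dataset)
        # logit rho bounded: near the lower bound (rho -> 0, no overdispersion)
        # the likelihood is flat in rho and the SE is profiled at the boundary
        bounds = [(-25, 25), (-25, 25), (-12, 12)]
        detect = [(-25, 25), (-25, 25), (-11.5, 11.5)]
        res = _ml_minimize(negll, self._start(dataset, _link(self.measure_)), bounds)
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2:
            return self
        hess = numeric_hessian(negll, res.x)
        cov, at_bound = covariance_with_active_bounds(hess, res.x, detect)
        if cov is None or at_bound[0] or at_bound[1]:
            return self
        est = float(res.x[1])
        se = math.sqrt(cov[1, 1]) if cov[1, 1] > 0 else math.nan
        df = self._df_from_rule(self.df_rule, dataset.k)
        if not math.isfinite(se) or se <= 0:
            return self
        ci = t_confidence_interval(est, se, df)
        if self._mark_converged(est, se, ci):
            self.df_ = df
            self.loglik_ = -float(res.fun)
            self.params_ = np.asarray(res.x, dtype=float)
            self.rho_ = float(expit(res.x[2]))
        return self


class BetaBinomialRandomEffect(BetaBinomialCommonRho):
    """Common-rho beta-binomial with a per-study random treatment effect (BBFR)."""

    method_name = "bbfr"

    def __init__(
        self,
        measure: str = "or",
        df_rule: str = "2k-2",
        rho_start: float = 0.1,
        sigma2_start: float = 0.01,
        quad_points: int = 1,
    ):
        super().__init__(measure=measure, df_rule=df_rule, rho_start=rho_start)
        self.sigma2_start = sigma2_start
        self.quad_points = quad_points

    @staticmethod
    def _bb_treat_parts(gamma, eta_base, rho, y, n, link):
        """Treatment-arm beta-binomial log likelihood and its first two
        derivatives with respect to gamma, vectorised over studies.

        Under the common-rho constraint alpha + beta = (1 - rho)/rho is
        constant in gamma, so only psi(y + alpha) - psi(alpha) and the
        mirrored beta terms vary.
        """
        eta = eta_base + gamma
        f = (1.0 - rho) / rho
        if link == "logit":
            mu = expit(eta)
            valid = (mu > 0.0) & (mu < 1.0)
            mu = np.clip(mu, 1e-300, 1 - 1e-16)
            dmu = mu * (1.0 - mu)
            d2mu = dmu * (1.0 - 2.0 * mu)
        else:
            valid = eta < 0.0
            mu = np.exp(np.where(valid, eta, -1.0))
            dmu = mu
            d2mu = mu
        a = mu * f
        b = (1.0 - mu) * f
        ll = betabin_logpmf(y, n, a, b)
        bracket = digamma(y + a) - digamma(a) - digamma(n - y + b) + digamma(b)
        d1 = f * dmu * bracket
        curve = polygamma(1, y + a) - polygamma(1, a) + polygamma(1, n - y + b) - polygamma(1, b)
        d2 = f * d2mu * bracket + (f * dmu) ** 2 * curve
        bad = ~(valid & np.isfinite(ll))
        ll = np.where(bad, -np.inf, ll)
        d1 = np.where(bad, 0.0, d1)
        d2 = np.where(bad, -1.0, d2)
        return ll, d1, d2

    def _marginal_treat_ll(self, eta_base, rho, sigma2, y, n, link, quad_points):
        """Log treatment-arm likelihood marginalised over gamma ~ N(0, sigma2),
        by adaptive Gauss-Hermite quadrature around the Newton mode."""
        if sigma2 < 1e-8:
            ll, _, _ = self._bb_treat_parts(np.zeros_like(y), eta_base, rho, y, n, link)
            return np.where(np.isfinite(ll), ll, -_PENALTY)
        g = np.zeros_like(y, dtype=float)
        max_step = max(2.0, 4.0 * math.sqrt(sigma2))
        for _ in range(40):
            ll, d1, d2 = self._bb_treat_parts(g, eta_base, rho, y, n, link)
            h1 = d1 - g / sigma2
            h2 = np.minimum(d2 - 1.0 / sigma2, -1e-12)
            step = np.clip(h1 / h2, -max_step, max_step)
            h_cur = ll - g**2 / (2 * sigma2)
            g_new = g - step
            ll_new = self._bb_treat_parts(g_new, eta_base, rho, y, n, link)[0] - g_new**2 / (
                2 * sigma2
            )
            shrink = 1.0
            for _ in range(15):
                worse = ~(ll_new >= h_cur - 1e-12) | ~np.isfinite(ll_new)
                if not np.any(worse):
                    break
                shrink *= 0.5
                g_new = np.where(worse, g - shrink * step, g_new)
                ll_new = self._bb_treat_parts(g_new, eta_base, rho, y, n, link)[0] - g_new**2 / (
                    2 * sigma2
                )
            g = g_new
            if np.max(np.abs(h1)) < 1e-9 or np.max(np.abs(step)) < 1e-10:
                break
        ll, _, d2 = self._bb_treat_parts(g, eta_base, rho, y, n, link)
        curv = 1.0 / sigma2 - d2
        h_mode = ll - g**2 / (2 * sigma2)
        if quad_points <= 1:  # Laplace
            out = h_mode - 0.5 * np.log(sigma2 * curv)
        else:
            nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
            scale = np.sqrt(2.0 / curv)
            g_q = g[:, None] + scale[:, None] * nodes[None, :]
            hq = (
                self._bb_treat_parts(
                    g_q, eta_base[:, None], rho, y[:, None], n[:, None], link
                )[0]
                - g_q**2 / (2 * sigma2)
                + nodes[None, :] ** 2
                + np.log(weights)[None, :]
            )
            out = logsumexp(hq, axis=1) + np.log(scale) - 0.5 * math.log(2 * math.pi * sigma2)
        return np.where(np.isfinite(out), out, -_PENALTY)

    def negloglik(self, params, dataset: MetaDataset) -> float:
        b0, bt, lrho, ls2 = params
        if abs(lrho) > 30 or abs(ls2) > 40:
            return _PENALTY
        rho = expit(lrho)
        sigma2 = math.exp(ls2)
        link = _link(self.measure_)
        mu_c, ok_c = _mean_from_link(b0, link)
        if not ok_c or not (0.0 < mu_c < 1.0):
            return _PENALTY
        a_c, b_c = _alpha_beta(mu_c, rho)
        c = dataset.counts()
        ll = betabin_logpmf(c[:, 2], c[:, 3], a_c, b_c).sum()
        eta_base = np.full(dataset.k, b0 + bt)
        ll += self._marginal_treat_ll(
            eta_base, rho, sigma2, c[:, 0], c[:, 1], link, self.quad_points
        ).sum()
        if not np.isfinite(ll) or ll <= -_PENALTY / 2:
            return _PENALTY
        return -ll

    def _start(self, dataset, link):
        base = super()._start(dataset, link)
        return np.append(base, math.log(self.sigma2_start))

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        self.n_studies_used_ = dataset.k
        c = dataset.counts()
        if c[:, 0].sum() == 0 or c[:, 2].sum() == 0:
            return self
        negll = lambda p: self.negloglik(p, dataset)
        bounds = [(-25, 25), (-25, 25), (-12, 12), (-23, 5)]
        res = _ml_minimize(negll, self._start(dataset, _link(self.measure_)), bounds, polish=False)
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2:
            return self
        # quadrature noise (~1e-6) corrupts small finite-difference steps, so
        # for a degenerate random effect the information is computed on the
        # exact sigma2 = 0 path with sigma2 profiled out
        detect3 = [(-25, 25), (-25, 25), (-11.5, 11.5)]
        if res.x[3] < math.log(1e-6):
            negll3 = lambda q: self.negloglik(np.append(q, -23.0), dataset)
            hess = numeric_hessian(negll3, res.x[:3])
            cov, at_bound = covariance_with_active_bounds(hess, res.x[:3], detect3)
        else:
            hess = numeric_hessian(negll, res.x)
            cov, at_bound = covariance_with_active_bounds(
                hess, res.x, detect3 + [(math.log(1e-6), 5)]
            )
        if cov is None or at_bound[0] or at_bound[1]:
            return self
        est = float(res.x[1])
        se = math.sqrt(cov[1, 1]) if cov[1, 1] > 0 else math.nan
        if not math.isfinite(se) or se <= 0:
            return self
        df = self._df_from_rule(self.df_rule, dataset.k)
        ci = t_confidence_interval(est, se, df)
        if self._mark_converged(est, se, ci):
            self.df_ = df
            self.loglik_ = -float(res.fun)
            self.params_ = np.asarray(res.x, dtype=float)
            self.rho_ = float(expit(res.x[2]))
            self.sigma2_ = float(math.exp(res.x[3]))
        return self


class BetaBinomialCommonBetaArms(MetaAnalysisEstimator):
    """Common-beta beta-binomial pooling arms across studies (BBCB1, OR only)."""

    method_name = "bbcb1"
    measure = "or"

    def __init__(self, df_rule: str = "2k-2"):
        self.df_rule = df_rule

    def negloglik(self, params, dataset: MetaDataset) -> float:
        """Parameterization (x1, x2, x3) = (log alpha_C/beta, log alpha_T/beta, log beta).

        x1 and x2 are the group-mean logits (logit of alpha_i/(alpha_i + beta));
        x3 alone controls overdispersion, so a homogeneous dataset drifts only
        in x3 (beta -> infinity) while the effect x2 - x1 stays identified.
        """
        x1, x2, x3 = params
        if max(abs(x1), abs(x2), abs(x3)) > 40:
            return _PENALTY
        b = math.exp(x3)
        a_c, a_t = b * math.exp(x1), b * math.exp(x2)
        c = dataset.counts()
        ll = betabin_logpmf(c[:, 2], c[:, 3], a_c, b).sum()
        ll += betabin_logpmf(c[:, 0], c[:, 1], a_t, b).sum()
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        self.n_studies_used_ = dataset.k
        c = dataset.counts()
        if c[:, 0].sum() == 0 or c[:, 2].sum() == 0:
            return self
        p_t = (c[:, 0].sum() + 0.5) / (c[:, 1].sum() + 1.0)
        p_c = (c[:, 2].sum() + 0.5) / (c[:, 3].sum() + 1.0)
        # moment start: beta ~ (1-mu)(1-rho)/rho at rho = 0.1
        b0 = (1.0 - p_c) * 9.0
        x0 = np.array([math.log(p_c / (1 - p_c)), math.log(p_t / (1 - p_t)), math.log(b0)])
        negll = lambda p: self.negloglik(p, dataset)
        bounds = [(-25, 25), (-25, 25), (-12, 15)]
        res = _ml_minimize(negll, x0, bounds)
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2:
            return self
        hess = numeric_hessian(negll, res.x)
        # beta -> infinity is the no-overdispersion boundary; profile it there
        detect = [(-25, 25), (-25, 25), (-11.5, 14.5)]
        cov, at_bound = covariance_with_active_bounds(hess, res.x, detect)
        if cov is None or at_bound[0] or at_bound[1]:
            return self
        # logit(alpha_i / (alpha_i + beta)) = log(alpha_i / beta), so the
        # treatment effect is x2 - x1 and the delta method reduces to a
        # linear contrast of the covariance.
        est = float(res.x[1] - res.x[0])
        var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
        if var <= 0 or not np.isfinite(var):
            return self
        se = math.sqrt(var)
        df = self._df_from_rule(self.df_rule, dataset.k)
        ci = t_confidence_interval(est, se, df)
        if self._mark_converged(est, se, ci):
            self.df_ = df
            self.loglik_ = -float(res.fun)
            self.beta_ = math.exp(res.x[2])
            self.alpha_c_ = self.beta_ * math.exp(res.x[0])
            self.alpha_t_ = self.beta_ * math.exp(res.x[1])
        return self


class BetaBinomialCommonBetaConditional(MetaAnalysisEstimator):
    """Common-beta model conditioning on each study's event total (BBCB2, OR only)."""

    method_name = "bbcb2"
    measure = "or"

    def __init__(self, df_rule: str = "2k-2"):
        self.df_rule = df_rule

    def negloglik(self, params, dataset: MetaDataset) -> float:
        b0, bt = params
        if abs(b0) > 40 or abs(bt) > 40:
            return _PENALTY
        c = dataset.counts()
        m = c[:, 0] + c[:, 2]
        use = m > 0
        if not np.any(use):
            return _PENALTY
        lam_t = c[use, 1] * math.exp(b0 + bt)
        lam_c = c[use, 3] * math.exp(b0)
        ll = betabin_logpmf(c[use, 0], m[use], lam_t, lam_c).sum()
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        self.n_studies_used_ = dataset.k
        c = dataset.counts()
        m = c[:, 0] + c[:, 2]
        if m.sum() == 0 or c[:, 0].sum() == 0 or c[:, 2].sum() == 0:
            return self
        p_t = (c[:, 0].sum() + 0.5) / (c[:, 1].sum() + 1.0)
        p_c = (c[:, 2].sum() + 0.5) / (c[:, 3].sum() + 1.0)
        x0 = np.array([math.log(p_c), math.log(p_t) - math.log(p_c)])
        negll = lambda p: self.negloglik(p, dataset)
        # the baseline rate b0 only enters through the dispersion scale
        # lambda_t + lambda_c, so b0 -> +inf is the no-overdispersion
        # boundary of this conditional likelihood and is profiled there
        # (a genuine log event rate is far below 10)
        bounds = [(-25, 12), (-25, 25)]
        detect = [(-24.5, 10.0), (-24.5, 24.5)]
        res = _ml_minimize(negll, x0, bounds)
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2:
            return self
        hess = numeric_hessian(negll, res.x)
        cov, at_bound = covariance_with_active_bounds(hess, res.x, detect)
        if cov is None or at_bound[1]:
            return self
        est = float(res.x[1])
        se = math.sqrt(cov[1, 1]) if cov[1, 1] > 0 else math.nan
        if not math.isfinite(se) or se <= 0:
            return self
        df = self._df_from_rule(self.df_rule, dataset.k)
        ci = t_confidence_interval(est, se, df)
        if self._mark_converged(est, se, ci):
            self.df_ = df
            self.loglik_ = -float(res.fun)
        return self


def fit_bbst(dataset, measure="or", df_rule="2k-2") -> MethodResult:
    return BetaBinomialCommonRho(measure=measure, df_rule=df_rule).fit(dataset).result_


def fit_bbfr(dataset, measure="or", df_rule="2k-2", quad_points=1) -> MethodResult:
    est = BetaBinomialRandomEffect(measure=measure, df_rule=df_rule, quad_points=quad_points)
    return est.fit(dataset).result_


def fit_bbcb1(dataset, df_rule="2k-2") -> MethodResult:
    return BetaBinomialCommonBetaArms(df_rule=df_rule).fit(dataset).result_


def fit_bbcb2(dataset, df_rule="2k-2") -> MethodResult:
    return BetaBinomialCommonBetaConditional(df_rule=df_rule).fit(dataset).result_
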