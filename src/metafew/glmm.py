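"""Laplace-approximated mixed logistic models for meta-analysis.

Two generalised linear mixed models on the arm-level binomial counts:

``MixedLogisticFixedIntercept`` (GLFR)
    g(pi_ki) = gamma_k + i*theta + i*eps_k with per-study fixed intercepts
    gamma_k and a random treatment effect eps_k ~ N(0, tau2).

``MixedLogisticRandomIntercept`` (GLRRI)
    gamma_k ~ N(gamma, sigma2_int) random intercepts plus an uncorrelated
    random treatment effect eps_k ~ N(0, tau2).

The random effects are integrated out per study with the Laplace
approximation (one adaptive quadrature node, the working default) or
adaptive Gauss-Hermite quadrature with more nodes.  Confidence intervals
are Wald intervals theta_hat +/- 1.96 * se on the log OR / log RR scale.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln, logit, logsumexp

from ._numutils import (
    covariance_with_active_bounds,
    numeric_hessian,
    numeric_hessian_from_grad,
)
from .base import MetaAnalysisEstimator
from .data import Measure, MetaDataset, MethodResult

__all__ = [
    "MixedLogisticFixedIntercept",
    "MixedLogisticRandomIntercept",
    "fit_glfr",
    "fit_glrri",
]

_PENALTY = 1e12
_TAU2_FLOOR = 1e-10
_Z975 = 1.959963984540054


def _binom_ll_parts(y, n, eta, link):
    """Binomial log likelihood, first and second derivative w.r.t. eta.

    For the log link the linear predictor must satisfy eta < 0 (pi < 1);
    violations return -inf likelihood so the caller can penalise.
    """
    lgcoef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    if link == "logit":
        p = expit(eta)
        ll = lgcoef + y * eta - n * np.logaddexp(0.0, eta)
        d1 = y - n * p
        d2 = -n * p * (1.0 - p)
        return ll, d1, d2
    # log link
    eta = np.asarray(eta, dtype=float)
    bad = eta >= -1e-12
    eta_s = np.where(bad, -1e-6, eta)
    p = np.exp(eta_s)
    om = -np.expm1(eta_s)  # 1 - p, accurate near 0
    ll = lgcoef + y * eta_s + (n - y) * np.log(om)
    r = p / om
    d1 = y - (n - y) * r
    d2 = -(n - y) * r / om
    ll = np.where(bad, -np.inf, ll)
    return ll, d1, d2


def _binom_ll(y, n, eta, link):
    return _binom_ll_parts(y, n, eta, link)[0]


def _binom_ll_d3(y, n, eta, link):
    """Third derivative of the binomial log likelihood w.r.t. eta."""
    if link == "logit":
        p = expit(eta)
        return -n * p * (1.0 - p) * (1.0 - 2.0 * p)
    eta = np.asarray(eta, dtype=float)
    eta_s = np.where(eta >= -1e-12, -1e-6, eta)
    p = np.exp(eta_s)
    om = -np.expm1(eta_s)
    return -(n - y) * p * (1.0 + p) / om**3


class MixedLogisticFixedIntercept(MetaAnalysisEstimator):
    """Fixed study intercepts, random treatment effect (GLFR)."""

    method_name = "glfr"

    def __init__(self, measure: str = "or", quad_points: int = 1, tau2_start: float = 0.1):
        self.measure = measure
        self.quad_points = quad_points
        self.tau2_start = tau2_start

    # -- treatment-arm marginal over eps ~ N(0, tau2), vectorised over studies
    @staticmethod
    def _laplace_mode(eta0, tau2, y, n, link):
        """Newton mode of h(eps) = llbin(eta0 + eps) - eps^2/(2 tau2)."""
        eps = np.zeros_like(eta0)
        max_step = max(2.0, 4.0 * math.sqrt(tau2))
        for _ in range(40):
            ll, d1, d2 = _binom_ll_parts(y, n, eta0 + eps, link)
            h1 = d1 - eps / tau2
            h2 = np.minimum(d2 - 1.0 / tau2, -1e-12)
            step = np.clip(h1 / h2, -max_step, max_step)
            h_cur = ll - eps**2 / (2 * tau2)
            eps_new = eps - step
            ll_new = _binom_ll(y, n, eta0 + eps_new, link) - eps_new**2 / (2 * tau2)
            shrink = 1.0
            for _ in range(15):
                worse = ~(ll_new >= h_cur - 1e-12) | ~np.isfinite(ll_new)
                if not np.any(worse):
                    break
                shrink *= 0.5
                eps_new = np.where(worse, eps - shrink * step, eps_new)
                ll_new = _binom_ll(y, n, eta0 + eps_new, link) - eps_new**2 / (2 * tau2)
            eps = eps_new
            if np.max(np.abs(h1)) < 1e-9 or np.max(np.abs(step)) < 1e-9:
                break
        return eps

    def _marginal_treat_ll(self, eta0, tau2, y, n, link, quad_points):
        """log int Bin(y; n, g^{-1}(eta0 + eps)) N(eps; 0, tau2) deps per study."""
        if tau2 < _TAU2_FLOOR:
            out = _binom_ll(y, n, eta0, link)
            return np.where(np.isfinite(out), out, -_PENALTY)
        eps = self._laplace_mode(eta0, tau2, y, n, link)
        ll, _, d2 = _binom_ll_parts(y, n, eta0 + eps, link)
        curv = 1.0 / tau2 - d2  # -h'' > 0 always for these links
        h_mode = ll - eps**2 / (2 * tau2)
        if quad_points <= 1:
            out = h_mode - 0.5 * np.log(tau2 * curv)
        else:
            nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
            scale = np.sqrt(2.0 / curv)  # per study
            eps_q = eps[:, None] + scale[:, None] * nodes[None, :]
            hq = (
                _binom_ll(y[:, None], n[:, None], eta0[:, None] + eps_q, link)
                - eps_q**2 / (2 * tau2)
                + nodes[None, :] ** 2
                + np.log(weights)[None, :]
            )
            out = logsumexp(hq, axis=1) + np.log(scale) - 0.5 * math.log(2 * math.pi * tau2)
        return np.where(np.isfinite(out), out, -_PENALTY)

    def _marginal_treat_laplace_grad(self, eta0, tau2, y, n, link):
        """Laplace marginal and its derivatives w.r.t. eta0 and tau2.

        Uses the envelope theorem for the mode value and implicit
        differentiation of the mode for the curvature (log-det) term.
        """
        if tau2 < _TAU2_FLOOR:
            ll, d1, _ = _binom_ll_parts(y, n, eta0, link)
            return ll, d1, np.zeros_like(ll)
        eps = self._laplace_mode(eta0, tau2, y, n, link)
        m = eta0 + eps
        ll, d1, d2 = _binom_ll_parts(y, n, m, link)
        d3 = _binom_ll_d3(y, n, m, link)
        curv = 1.0 / tau2 - d2
        marg = ll - eps**2 / (2 * tau2) - 0.5 * np.log(tau2 * curv)
        dm_deta0 = (1.0 / tau2) / curv  # 1 + deps/deta0
        dmarg_deta0 = d1 + 0.5 * d3 * dm_deta0 / curv
        deps_dtau2 = eps / (tau2**2 * curv)
        dcurv_dtau2 = -1.0 / tau2**2 - d3 * deps_dtau2
        dmarg_dtau2 = eps**2 / (2 * tau2**2) - 0.5 / tau2 - 0.5 * dcurv_dtau2 / curv
        return marg, dmarg_deta0, dmarg_dtau2

    def _unpack(self, params, k):
        gamma = np.asarray(params[:k], dtype=float)
        theta = float(params[k])
        ltau2 = float(params[k + 1])
        return gamma, theta, ltau2

    def negloglik(self, params, dataset: MetaDataset) -> float:
        k = dataset.k
        gamma, theta, ltau2 = self._unpack(params, k)
        if abs(ltau2) > 40 or np.max(np.abs(gamma)) > 40 or abs(theta) > 40:
            return _PENALTY
        tau2 = math.exp(ltau2)
        link = "logit" if self.measure_ == Measure.OR else "log"
        c = dataset.counts()
        ll_c = _binom_ll(c[:, 2], c[:, 3], gamma, link)
        if not np.all(np.isfinite(ll_c)):
            return _PENALTY
        ll_t = self._marginal_treat_ll(gamma + theta, tau2, c[:, 0], c[:, 1], link, self.quad_points)
        total = ll_c.sum() + ll_t.sum()
        if not np.isfinite(total) or total <= -_PENALTY / 2:
            return _PENALTY
        return -float(total)

    def negloglik_and_grad(self, params, dataset: MetaDataset):
        """Value and analytic gradient (Laplace path, one quadrature node)."""
        k = dataset.k
        gamma, theta, ltau2 = self._unpack(params, k)
        grad0 = np.zeros(k + 2)
        if abs(ltau2) > 40 or np.max(np.abs(gamma)) > 40 or abs(theta) > 40:
            return _PENALTY, grad0
        tau2 = math.exp(ltau2)
        link = "logit" if self.measure_ == Measure.OR else "log"
        c = dataset.counts()
        ll_c, d1_c, _ = _binom_ll_parts(c[:, 2], c[:, 3], gamma, link)
        if not np.all(np.isfinite(ll_c)):
            return _PENALTY, grad0
        marg, dm_eta, dm_t2 = self._marginal_treat_laplace_grad(
            gamma + theta, tau2, c[:, 0], c[:, 1], link
        )
        total = ll_c.sum() + marg.sum()
        if not np.isfinite(total) or total <= -_PENALTY / 2:
            return _PENALTY, grad0
        grad = np.empty(k + 2)
        grad[:k] = -(d1_c + dm_eta)
        grad[k] = -dm_eta.sum()
        grad[k + 1] = -(dm_t2 * tau2).sum()
        return -float(total), grad

    def _start(self, dataset: MetaDataset, link):
        c = dataset.counts()
        p_c = (c[:, 2] + 0.5) / (c[:, 3] + 1.0)
        p_t = (c[:, 0].sum() + 0.5) / (c[:, 1].sum() + 1.0)
        p_cbar = (c[:, 2].sum() + 0.5) / (c[:, 3].sum() + 1.0)
        g = logit if link == "logit" else np.log
        gamma0 = g(p_c)
        theta0 = float(g(p_t) - g(p_cbar))
        return np.concatenate([gamma0, [theta0, math.log(self.tau2_start)]])

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        self.n_studies_used_ = dataset.k
        c = dataset.counts()
        # complete separation across the whole arm group: theta diverges
        if (
            c[:, 0].sum() == 0
            or c[:, 2].sum() == 0
            or c[:, 0].sum() == c[:, 1].sum()
            or c[:, 2].sum() == c[:, 3].sum()
        ):
            return self
        link = "logit" if self.measure_ == Measure.OR else "log"
        negll = lambda p: self.negloglik(p, dataset)
        k = dataset.k
        bounds = [(-30, 30)] * k + [(-30, 30), (-23, 6)]
        if self.quad_points <= 1:
            fun = lambda p: self.negloglik_and_grad(p, dataset)
            res = optimize.minimize(
                fun, self._start(dataset, link), method="L-BFGS-B", jac=True, bounds=bounds
            )
        else:
            res = optimize.minimize(
                negll, self._start(dataset, link), method="L-BFGS-B", bounds=bounds
            )
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2:
            return self
        if self.quad_points <= 1:
            grad = lambda p: self.negloglik_and_grad(p, dataset)[1]
            hess = numeric_hessian_from_grad(grad, res.x)
        else:
            hess = numeric_hessian(negll, res.x)
        # a variance transform near its floor (tau2 < 1e-6) leaves the
        # likelihood flat in log tau2 and is profiled out.  Intercepts of
        # double-zero (or all-events) studies diverge to the boundary, where
        # such studies contribute no information about theta: they are
        # profiled out exactly.  Any other intercept, or theta, on a bound
        # means a failed fit.
        uninformative = ((c[:, 0] == 0) & (c[:, 2] == 0)) | (
            (c[:, 0] == c[:, 1]) & (c[:, 2] == c[:, 3])
        )
        force = np.concatenate([uninformative, [False, False]])
        detect = [(-25.0, 25.0)] * (k + 1) + [(math.log(1e-6), 5.9)]
        cov, at_bound = covariance_with_active_bounds(hess, res.x, detect, force=force)
        if cov is None or (at_bound[:k] & ~uninformative).any() or at_bound[k]:
            return self
        est = float(res.x[k])
        var = cov[k, k]
        if var <= 0 or not np.isfinite(var):
            return self
        se = math.sqrt(var)
        ci = (est - _Z975 * se, est + _Z975 * se)
        if self._mark_converged(est, se, ci):
            self.tau2_ = float(max(math.exp(res.x[k + 1]), 0.0))
            if self.tau2_ <= _TAU2_FLOOR:
                self.tau2_ = 0.0
            self.loglik_ = -float(res.fun)
            self.gamma_ = np.asarray(res.x[:k], dtype=float)
        return self


class MixedLogisticRandomIntercept(MetaAnalysisEstimator):
    """Random study intercepts and random treatment effect (GLRRI)."""

    method_name = "glrri"

    def __init__(
        self,
        measure: str = "or",
        quad_points: int = 1,
        tau2_start: float = 0.1,
        sigma2_start: float = 0.1,
    ):
        self.measure = measure
        self.quad_points = quad_points
        self.tau2_start = tau2_start
        self.sigma2_start = sigma2_start

    def _joint_mode(self, gamma, theta, s2, t2, c, link):
        """Per-study 2-D Newton for the mode of the (u, eps) joint integrand."""
        k = c.shape[0]
        u = np.zeros(k)
        e = np.zeros(k)
        y_t, n_t, y_c, n_c = c[:, 0], c[:, 1], c[:, 2], c[:, 3]

        def h_val(u, e):
            llc = _binom_ll(y_c, n_c, gamma + u, link)
            llt = _binom_ll(y_t, n_t, gamma + u + theta + e, link)
            return llc + llt - u**2 / (2 * s2) - e**2 / (2 * t2)

        for _ in range(100):
            llc, d1c, d2c = _binom_ll_parts(y_c, n_c, gamma + u, link)
            llt, d1t, d2t = _binom_ll_parts(y_t, n_t, gamma + u + theta + e, link)
            gu = d1c + d1t - u / s2
            ge = d1t - e / t2
            huu = d2c + d2t - 1.0 / s2
            hue = d2t
            hee = d2t - 1.0 / t2
            det = huu * hee - hue**2
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            du = (gu * hee - ge * hue) / det
            de = (ge * huu - gu * hue) / det
            h_cur = llc + llt - u**2 / (2 * s2) - e**2 / (2 * t2)
            shrink = 1.0
            u_new, e_new = u - du, e - de
            h_new = h_val(u_new, e_new)
            for _ in range(30):
                worse = ~(h_new >= h_cur - 1e-12) | ~np.isfinite(h_new)
                if not np.any(worse):
                    break
                shrink *= 0.5
                u_new = np.where(worse, u - shrink * du, u_new)
                e_new = np.where(worse, e - shrink * de, e_new)
                h_new = h_val(u_new, e_new)
            u, e = u_new, e_new
            if max(np.max(np.abs(du)), np.max(np.abs(de))) < 1e-9:
                break
        return u, e

    def negloglik(self, params, dataset: MetaDataset) -> float:
        gamma, theta, ls2, lt2 = (float(v) for v in params)
        if max(abs(gamma), abs(theta)) > 40 or max(abs(ls2), abs(lt2)) > 40:
            return _PENALTY
        s2 = max(math.exp(ls2), _TAU2_FLOOR)
        t2 = max(math.exp(lt2), _TAU2_FLOOR)
        link = "logit" if self.measure_ == Measure.OR else "log"
        c = dataset.counts()
        u, e = self._joint_mode(gamma, theta, s2, t2, c, link)
        llc, _, d2c = _binom_ll_parts(c[:, 2], c[:, 3], gamma + u, link)
        llt, _, d2t = _binom_ll_parts(c[:, 0], c[:, 1], gamma + u + theta + e, link)
        huu = d2c + d2t - 1.0 / s2
        hue = d2t
        hee = d2t - 1.0 / t2
        det = huu * hee - hue**2  # positive at a proper mode
        if np.any(det <= 0) or not np.all(np.isfinite(det)):
            return _PENALTY
        h_mode = llc + llt - u**2 / (2 * s2) - e**2 / (2 * t2)
        # 2-D Laplace: log det of the negated Hessian and the normal constants
        ll = h_mode - 0.5 * (np.log(det) + math.log(s2) + math.log(t2))
        if self.quad_points > 1:
            ll = self._agq_correction(gamma, theta, s2, t2, c, link, u, e, huu, hue, hee)
        total = ll.sum()
        if not np.isfinite(total):
            return _PENALTY
        return -float(total)

    def _agq_correction(self, gamma, theta, s2, t2, c, link, u, e, huu, hue, hee):
        """Product-rule adaptive Gauss-Hermite over the 2-D random effect."""
        q = self.quad_points
        nodes, weights = np.polynomial.hermite.hermgauss(q)
        y_t, n_t, y_c, n_c = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
        out = np.empty(c.shape[0])
        for i in range(c.shape[0]):
            neg_h = -np.array([[huu[i], hue[i]], [hue[i], hee[i]]])
            try:
                chol = np.linalg.cholesky(np.linalg.inv(neg_h))
            except np.linalg.LinAlgError:
                out[i] = -_PENALTY
                continue
            zz1, zz2 = np.meshgrid(nodes, nodes, indexing="ij")
            z = np.stack([zz1.ravel(), zz2.ravel()])
            pts = np.array([u[i], e[i]])[:, None] + math.sqrt(2.0) * (chol @ z)
            uu, ee = pts[0], pts[1]
            hq = (
                _binom_ll(y_c[i], n_c[i], gamma + uu, link)
                + _binom_ll(y_t[i], n_t[i], gamma + uu + theta + ee, link)
                - uu**2 / (2 * s2)
                - ee**2 / (2 * t2)
                + zz1.ravel() ** 2
                + zz2.ravel() ** 2
                + np.log(np.outer(weights, weights)).ravel()
            )
            logdet_chol = float(np.log(np.diag(chol)).sum())
            out[i] = (
                logsumexp(hq)
                + math.log(2.0)
                + logdet_chol
                - math.log(2 * math.pi)
                - 0.5 * (math.log(s2) + math.log(t2))
            )
        return out

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        self.n_studies_used_ = dataset.k
        if dataset.k < 2:
            return self
        c = dataset.counts()
        if (
            c[:, 0].sum() == 0
            or c[:, 2].sum() == 0
            or c[:, 0].sum() == c[:, 1].sum()
            or c[:, 2].sum() == c[:, 3].sum()
        ):
            return self
        link = "logit" if self.measure_ == Measure.OR else "log"
        p_t = (c[:, 0].sum() + 0.5) / (c[:, 1].sum() + 1.0)
        p_c = (c[:, 2].sum() + 0.5) / (c[:, 3].sum() + 1.0)
        g = logit if link == "logit" else np.log
        x0 = np.array(
            [
                float(g(p_c)),
                float(g(p_t) - g(p_c)),
                math.log(self.sigma2_start),
                math.log(self.tau2_start),
            ]
        )
        negll = lambda p: self.negloglik(p, dataset)
        bounds = [(-30, 30), (-30, 30), (-23, 6), (-23, 6)]
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun) or res.fun >= _PENALTY / 2:
            return self
        hess = numeric_hessian(negll, res.x)
        detect = [(-29.5, 29.5)] * 2 + [(math.log(1e-6), 5.9)] * 2
        cov, at_bound = covariance_with_active_bounds(hess, res.x, detect)
        if cov is None or at_bound[0] or at_bound[1]:
            return self
        est = float(res.x[1])
        var = cov[1, 1]
        if var <= 0 or not np.isfinite(var):
            return self
        se = math.sqrt(var)
        ci = (est - _Z975 * se, est + _Z975 * se)
        if self._mark_converged(est, se, ci):
            self.tau2_ = float(math.exp(res.x[3]))
            if self.tau2_ <= _TAU2_FLOOR:
                self.tau2_ = 0.0
            self.sigma2_int_ = float(math.exp(res.x[2]))
            self.loglik_ = -float(res.fun)
        return self


def fit_glfr(dataset, measure="or", quad_points=1) -> MethodResult:
    return MixedLogisticFixedIntercept(measure=measure, quad_points=quad_points).fit(dataset).result_


def fit_glrri(dataset, measure="or", quad_points=1) -> MethodResult:
    return MixedLogisticRandomIntercept(measure=measure, quad_points=quad_points).fit(dataset).result_
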