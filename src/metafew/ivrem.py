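"""Inverse-variance fixed/random effects machinery.

Implements the fixed-effect pooled estimate, Cochran's Q, the
DerSimonian-Laird moment estimator of the between-study variance, the
Paule-Mandel estimator (root of the generalised Q statistic at its
expectation K - 1), and the Hartung-Knapp-Sidik-Jonkman interval with the
ad-hoc modification q* = max{1, q} applied whenever the unmodified HKSJ
interval would be narrower than the DerSimonian-Laird interval.

Per-study log effects use the inverse-variance continuity policy: 0.5 added
to all four cells of studies with a zero cell; double-zero studies excluded.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .base import MetaAnalysisEstimator
from .data import EffectEstimate, MethodResult, per_study_log_effects

__all__ = [
    "fixed_effect",
    "cochran_q",
    "dsl_tau2",
    "pm_tau2",
    "DerSimonianLaird",
    "HartungKnappSidikJonkman",
    "fit_dsl",
    "fit_hksj",
]

_Z975 = 1.959963984540054


def _arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    inc = [e for e in effects if e.included]
    if not inc:
        raise ValueError("no included effect estimates")
    theta = np.array([e.theta_hat_k for e in inc], dtype=float)
    var = np.array([e.var_k for e in inc], dtype=float)
    if np.any(var <= 0):
        raise ValueError("non-positive within-study variance")
    return theta, var


def fixed_effect(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Inverse-variance weighted pooled effect and its standard error."""
    theta, var = _arrays(effects)
    w = 1.0 / var
    pooled = float(np.sum(w * theta) / np.sum(w))
    return pooled, float(math.sqrt(1.0 / np.sum(w)))


def cochran_q(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Cochran's heterogeneity statistic and its chi-square p-value (K - 1 df)."""
    theta, var = _arrays(effects)
    k = theta.size
    if k < 2:
        raise ValueError("Cochran's Q needs at least 2 included studies")
    w = 1.0 / var
    pooled = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - pooled) ** 2))
    p = float(stats.chi2.sf(q, k - 1))
    return q, p


def dsl_tau2(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimator, truncated at zero."""
    theta, var = _arrays(effects)
    k = theta.size
    if k < 2:
        return 0.0
    w = 1.0 / var
    q, _ = cochran_q(effects)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return float(max(0.0, (q - (k - 1)) / denom))


def _gen_q(tau2: float, theta: np.ndarray, var: np.ndarray) -> float:
    w = 1.0 / (var + tau2)
    pooled = np.sum(w * theta) / np.sum(w)
    return float(np.sum(w * (theta - pooled) ** 2))


def pm_tau2(effects: Sequence[EffectEstimate], tol: float = 1e-8, max_iter: int = 200) -> float:
    """Paule-Mandel estimator: tau2 solving Q(tau2) = K - 1, or 0 if none.

    Q(tau2) is strictly decreasing, so the root (when Q(0) > K - 1) is unique
    and found by bracketing with a geometrically grown upper bound.
    """
    theta, var = _arrays(effects)
    k = theta.size
    if k < 2:
        return 0.0
    target = float(k - 1)
    if _gen_q(0.0, theta, var) <= target:
        return 0.0
    hi = max(float(np.mean(var)), 1e-3)
    it = 0
    while _gen_q(hi, theta, var) > target:
        hi *= 2.0
        it += 1
        if it > max_iter:
            raise RuntimeError(
                f"Paule-Mandel bracketing failed after {max_iter} doublings (hi={hi:g})"
            )
    root = optimize.brentq(lambda t: _gen_q(t, theta, var) - target, 0.0, hi, xtol=tol)
    return float(max(0.0, root))


class DerSimonianLaird(MetaAnalysisEstimator):
    """DerSimonian-Laird random-effects model with a normal 95% interval."""

    method_name = "dsl"

    def __init__(self, measure: str = "or"):
        self.measure = measure

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        try:
            effects = per_study_log_effects(dataset, self.measure_, policy="ivrem")
        except ValueError:
            return self
        inc = [e for e in effects if e.included]
        self.n_studies_used_ = len(inc)
        tau2 = dsl_tau2(effects) if len(inc) >= 2 else 0.0
        theta, var = _arrays(effects)
        w = 1.0 / (var + tau2)
        est = float(np.sum(w * theta) / np.sum(w))
        se = float(math.sqrt(1.0 / np.sum(w)))
        ci = (est - _Z975 * se, est + _Z975 * se)
        if self._mark_converged(est, se, ci):
            self.tau2_ = float(tau2)
            self.effects_ = effects
        return self


class HartungKnappSidikJonkman(MetaAnalysisEstimator):
    """HKSJ interval with Paule-Mandel weights and the ad-hoc modification.

    The scaling factor q is replaced by max{1, q} whenever the unmodified
    interval would be narrower than the DerSimonian-Laird interval computed
    on the same data.
    """

    method_name = "hksj"

    def __init__(self, measure: str = "or"):
        self.measure = measure

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        try:
            effects = per_study_log_effects(dataset, self.measure_, policy="ivrem")
        except ValueError:
            return self
        inc = [e for e in effects if e.included]
        self.n_studies_used_ = len(inc)
        k = len(inc)
        if k < 2:
            return self
        dsl = DerSimonianLaird(measure=self.measure).fit(dataset)
        tau2 = pm_tau2(effects)
        theta, var = _arrays(effects)
        w = 1.0 / (var + tau2)
        est = float(np.sum(w * theta) / np.sum(w))
        sigma = float(math.sqrt(1.0 / np.sum(w)))
        q = float(np.sum(w * (theta - est) ** 2) / (k - 1))
        tq = stats.t.ppf(0.975, k - 1)
        half = tq * math.sqrt(q) * sigma
        ad_hoc = False
        if dsl.converged_ and 2 * half < (dsl.ci_high_ - dsl.ci_low_):
            q_star = max(1.0, q)
            half = tq * math.sqrt(q_star) * sigma
            ad_hoc = True
            q = q_star
        se = math.sqrt(q) * sigma
        ci = (est - half, est + half)
        if self._mark_converged(est, se, ci):
            self.df_ = k - 1
            self.tau2_ = float(tau2)
            self.q_factor_ = float(q)
            self.ad_hoc_applied_ = ad_hoc
            self.effects_ = effects
        return self


def fit_dsl(dataset, measure="or") -> MethodResult:
    return DerSimonianLaird(measure=measure).fit(dataset).result_


def fit_hksj(dataset, measure="or") -> MethodResult:
    return HartungKnappSidikJonkman(measure=measure).fit(dataset).result_
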