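"""Scikit-learn-style base class shared by all meta-analysis estimators.

Every method is an estimator with ``fit(X)`` where X is a ``MetaDataset``, a
(K, 4) count array with columns ``y_t, n_t, y_c, n_c``, or a DataFrame with
those columns.  Fitted attributes carry a trailing underscore:

- ``effect_`` pooled log effect (log OR or log RR)
- ``se_`` its standard error
- ``ci_low_``, ``ci_high_`` 95% confidence bounds on the log scale
- ``converged_`` whether the fit met the convergence accounting rule
- ``tau2_``, ``df_``, ``n_studies_used_``, ``loglik_`` where applicable

``result_`` assembles these into a :class:`~metafew.data.MethodResult`.
Estimators never raise on a failed numerical fit: they record
``converged_ = False`` so that large simulation sweeps can keep running.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator

from .data import Measure, MetaDataset, MethodResult, _coerce_dataset, validate_dataset

__all__ = ["MetaAnalysisEstimator"]


class MetaAnalysisEstimator(BaseEstimator):
    """Base class for pooled-effect estimators on two-arm binary studies."""

    method_name: str = "base"

    def _validate_input(self, X) -> MetaDataset:
        dataset = _coerce_dataset(X)
        return validate_dataset(dataset)

    # subclasses set these in fit()
    def _init_fitted(self, dataset: MetaDataset) -> None:
        self.k_ = dataset.k
        self.effect_ = math.nan
        self.se_ = math.nan
        self.ci_low_ = math.nan
        self.ci_high_ = math.nan
        self.df_ = None
        self.tau2_ = None
        self.converged_ = False
        self.n_studies_used_ = 0
        self.loglik_ = None

    def _mark_converged(self, est: float, se: float, ci: tuple[float, float]) -> bool:
        """Convergence accounting: finite estimate AND finite positive SE."""
        ok = (
            est is not None
            and se is not None
            and math.isfinite(est)
            and math.isfinite(se)
            and se > 0
            and all(math.isfinite(v) for v in ci)
        )
        if ok:
            self.effect_ = float(est)
            self.se_ = float(se)
            self.ci_low_, self.ci_high_ = float(ci[0]), float(ci[1])
            self.converged_ = True
        return ok

    @property
    def measure_(self) -> Measure:
        return Measure(getattr(self, "measure", "or"))

    @property
    def result_(self) -> MethodResult:
        if not hasattr(self, "converged_"):
            raise AttributeError("estimator is not fitted")
        res = MethodResult(method=self.method_name, measure=self.measure_)
        res.converged = self.converged_
        res.n_studies_used = self.n_studies_used_
        res.df = self.df_
        res.tau2_hat = self.tau2_
        res.loglik = self.loglik_
        if self.converged_:
            res.est = self.effect_
            res.se = self.se_
            res.ci_lo = self.ci_low_
            res.ci_hi = self.ci_high_
        return res

    def fit(self, X, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    @staticmethod
    def _df_from_rule(df_rule: str, k: int) -> int:
        if df_rule in ("k-1", "K_minus_1"):
            return max(k - 1, 1)
        if df_rule in ("2k-2", "twoK_minus_2"):
            return max(2 * k - 2, 1)
        raise ValueError(f"unknown df_rule {df_rule!r}; use 'k-1' or '2k-2'")
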