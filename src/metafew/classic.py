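"""Mantel-Haenszel, Peto, and collapsed-table estimators.

Zero-study policies differ deliberately between the three methods:

- Mantel-Haenszel applies no continuity correction; any study with a zero
  cell is dropped (a configuration switch restores the conventional
  behaviour of keeping single-zero studies, off by default).
- The Peto one-step estimator includes single-zero studies by construction
  and drops only studies whose hypergeometric variance is zero (which
  covers double-zero studies).
- The collapsed table pools all studies into one 2x2 table, adding 0.5 to
  all four cells only if the pooled table has a zero cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .base import MetaAnalysisEstimator
from .data import Measure, MethodResult

__all__ = [
    "FourFoldTable",
    "MantelHaenszel",
    "PetoOddsRatio",
    "CollapsedTable",
    "fit_mh",
    "fit_peto",
    "fit_collapsed",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class FourFoldTable:
    """One 2x2 table: a = treatment events, b = treatment non-events,
    c = control events, d = control non-events (0.5-corrected reals allowed)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


class MantelHaenszel(MetaAnalysisEstimator):
    """Mantel-Haenszel pooled odds ratio with the Robins-Breslow-Greenland SE."""

    method_name = "mh"
    measure = "or"

    def __init__(self, drop_zero_cell_studies: bool = True):
        self.drop_zero_cell_studies = drop_zero_cell_studies

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        c = dataset.counts()
        a = c[:, 0]
        b = c[:, 1] - c[:, 0]
        cc = c[:, 2]
        d = c[:, 3] - c[:, 2]
        if self.drop_zero_cell_studies:
            keep = (a > 0) & (b > 0) & (cc > 0) & (d > 0)
        else:
            keep = ~((a == 0) & (cc == 0)) & ~((b == 0) & (d == 0))
        a, b, cc, d = a[keep], b[keep], cc[keep], d[keep]
        self.n_studies_used_ = int(keep.sum())
        if self.n_studies_used_ == 0:
            return self
        n = a + b + cc + d
        r = a * d / n
        s = b * cc / n
        if s.sum() == 0 or r.sum() == 0:
            return self
        est = float(math.log(r.sum() / s.sum()))
        # Robins-Breslow-Greenland variance of the log MH odds ratio
        p = (a + d) / n
        q = (b + cc) / n
        sr, ss = r.sum(), s.sum()
        var = (
            np.sum(p * r) / (2 * sr**2)
            + np.sum(p * s + q * r) / (2 * sr * ss)
            + np.sum(q * s) / (2 * ss**2)
        )
        if var <= 0 or not np.isfinite(var):
            return self
        se = float(math.sqrt(var))
        ci = (est - _Z975 * se, est + _Z975 * se)
        self._mark_converged(est, se, ci)
        return self


class PetoOddsRatio(MetaAnalysisEstimator):
    """Peto one-step pooled odds ratio from hypergeometric moments."""

    method_name = "peto"
    measure = "or"

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        c = dataset.counts()
        y_t, n_t, y_c, n_c = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
        n = n_t + n_c
        m = y_t + y_c
        o = y_t
        e = m * n_t / n
        with np.errstate(divide="ignore", invalid="ignore"):
            v = e * ((n - m) / n) * (n_c / (n - 1.0))
        v = np.where(np.isfinite(v), v, 0.0)
        keep = v > 0
        self.n_studies_used_ = int(keep.sum())
        sv = v[keep].sum()
        if sv <= 0:
            return self
        est = float(np.sum(o[keep] - e[keep]) / sv)
        se = float(1.0 / math.sqrt(sv))
        ci = (est - _Z975 * se, est + _Z975 * se)
        self._mark_converged(est, se, ci)
        return self


class CollapsedTable(MetaAnalysisEstimator):
    """Single pooled 2x2 table, ignoring stratification by study."""

    method_name = "coll"

    def __init__(self, measure: str = "or"):
        self.measure = measure

    def fit(self, X, y=None):
        dataset = self._validate_input(X)
        self._init_fitted(dataset)
        self.n_studies_used_ = dataset.k
        c = dataset.counts()
        a = float(c[:, 0].sum())
        b = float((c[:, 1] - c[:, 0]).sum())
        cc = float(c[:, 2].sum())
        d = float((c[:, 3] - c[:, 2]).sum())
        self.corrected_ = False
        if min(a, b, cc, d) == 0.0:
            a, b, cc, d = a + 0.5, b + 0.5, cc + 0.5, d + 0.5
            self.corrected_ = True
        self.pooled_table_ = FourFoldTable(a, b, cc, d)
        if self.measure_ == Measure.OR:
            est = math.log(a * d / (b * cc))
            var = 1 / a + 1 / b + 1 / cc + 1 / d
        else:
            n_t, n_c = a + b, cc + d
            est = math.log((a / n_t) / (cc / n_c))
            var = 1 / a - 1 / n_t + 1 / cc - 1 / n_c
        if var <= 0 or not math.isfinite(var) or not math.isfinite(est):
            return self
        se = math.sqrt(var)
        ci = (est - _Z975 * se, est + _Z975 * se)
        self._mark_converged(est, se, ci)
        return self


def fit_mh(dataset) -> MethodResult:
    return MantelHaenszel().fit(dataset).result_


def fit_peto(dataset) -> MethodResult:
    return PetoOddsRatio().fit(dataset).result_


def fit_collapsed(dataset, measure="or") -> MethodResult:
    return CollapsedTable(measure=measure).fit(dataset).result_
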