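"""Performance measures over replication-level simulation results.

All measures are computed over R, the converged replications of a method:
bias (log scale), percentage bias (H1 only), coverage of the true effect by
the 95% CI, CI length, and power (H1 only; fraction of CIs excluding zero).
Quartiles use linear interpolation (type 7), the numpy default.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["summarize", "sensitivity_subset"]

_REQUIRED = ["method", "est", "ci_lo", "ci_hi", "converged", "theta_true"]


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    if x.size == 0:
        return math.nan, math.nan, math.nan
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    return float(q1), float(med), float(q3)


def summarize(results: pd.DataFrame, hypothesis: str = "h0") -> pd.DataFrame:
    """One summary row per method: R, bias and CI-length quartiles, coverage,
    and under H1 percentage bias and power."""
    missing = [c for c in _REQUIRED if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    hypothesis = hypothesis.lower()
    is_h1 = hypothesis == "h1"
    rows = []
    for method, grp in results.groupby("method", sort=False):
        conv = grp[grp["converged"].astype(bool)]
        r = len(conv)
        row: dict = {"method": method, "R": r, "n_reps": len(grp)}
        if r == 0:
            row.update(
                bias_q1=math.nan, bias_med=math.nan, bias_q3=math.nan,
                coverage=math.nan, ci_len_q1=math.nan, ci_len_med=math.nan,
                ci_len_q3=math.nan,
            )
            if is_h1:
                row.update(
                    pct_bias_q1=math.nan, pct_bias_med=math.nan,
                    pct_bias_q3=math.nan, power=math.nan,
                )
            rows.append(row)
            continue
        bias = (conv["est"] - conv["theta_true"]).to_numpy(dtype=float)
        row["bias_q1"], row["bias_med"], row["bias_q3"] = _quartiles(bias)
        covered = (conv["ci_lo"] <= conv["theta_true"]) & (conv["theta_true"] <= conv["ci_hi"])
        row["coverage"] = float(100.0 * covered.mean())
        length = (conv["ci_hi"] - conv["ci_lo"]).to_numpy(dtype=float)
        row["ci_len_q1"], row["ci_len_med"], row["ci_len_q3"] = _quartiles(length)
        if is_h1:
            theta = conv["theta_true"].to_numpy(dtype=float)
            defined = np.abs(theta) > 1e-12
            pct = 100.0 * bias[defined] / theta[defined]
            row["pct_bias_q1"], row["pct_bias_med"], row["pct_bias_q3"] = _quartiles(pct)
            excl0 = (conv["ci_lo"] > 0.0) | (conv["ci_hi"] < 0.0)
            row["power"] = float(100.0 * excl0.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_subset(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Replications with no statistically significant heterogeneity
    (Cochran's Q p-value > alpha); feeds :func:`summarize` unchanged."""
    if "q_pvalue" not in results.columns:
        raise ValueError("results table missing the q_pvalue column")
    kept = results[results["q_pvalue"] > alpha]
    if kept.empty:
        raise ValueError(f"empty sensitivity subset at alpha={alpha}")
    return kept
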