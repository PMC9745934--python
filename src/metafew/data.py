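"""Core data model for two-arm binary meta-analysis.

A meta-analysis here is a collection of K independent two-arm studies, each
summarised by a 2x2 table: ``y_t`` events out of ``n_t`` participants in the
treatment arm and ``y_c`` events out of ``n_c`` in the control arm.  The
module provides the containers shared by every estimator, zero-study
classification, per-study log effect estimates with the inverse-variance
continuity-correction policy, and CSV input/output.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Measure",
    "ZeroClass",
    "StudyRecord",
    "SimulationTruth",
    "MetaDataset",
    "EffectEstimate",
    "MethodResult",
    "validate_dataset",
    "classify_zero_studies",
    "per_study_log_effects",
    "read_dataset_csv",
    "write_results_csv",
    "results_to_frame",
]


class Measure(str, enum.Enum):
    """Effect measure: odds ratio (logit link) or relative risk (log link)."""

    OR = "or"
    RR = "rr"


class ZeroClass(str, enum.Enum):
    NONE = "none"
    SINGLE_ZERO = "single_zero"
    DOUBLE_ZERO = "double_zero"


@dataclass(frozen=True)
class StudyRecord:
    """One study's 2x2 table.

    Arm coding follows the convention i = 1 for treatment, i = 0 for control.
    """

    study_id: str
    y_t: int
    n_t: int
    y_c: int
    n_c: int

    @property
    def n(self) -> int:
        return self.n_t + self.n_c


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters attached to a simulated meta-analysis."""

    measure: Measure
    theta_true: float
    pi_c_true: float
    tau2_true: float
    delta_k: tuple[float, ...]
    hypothesis: str  # "h0" or "h1"


@dataclass(frozen=True)
class MetaDataset:
    """Ordered collection of studies, optionally carrying simulation truth."""

    studies: tuple[StudyRecord, ...]
    truth: SimulationTruth | None = None

    def __init__(self, studies: Iterable[StudyRecord], truth: SimulationTruth | None = None):
        object.__setattr__(self, "studies", tuple(studies))
        object.__setattr__(self, "truth", truth)

    @property
    def k(self) -> int:
        return len(self.studies)

    def counts(self) -> np.ndarray:
        """(K, 4) integer array with columns y_t, n_t, y_c, n_c."""
        return np.array(
            [[s.y_t, s.n_t, s.y_c, s.n_c] for s in self.studies], dtype=float
        ).reshape(-1, 4)

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[Sequence[float]] | np.ndarray,
        truth: SimulationTruth | None = None,
    ) -> "MetaDataset":
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("counts must be a (K, 4) array: y_t, n_t, y_c, n_c")
        studies = [
            StudyRecord(str(i + 1), int(r[0]), int(r[1]), int(r[2]), int(r[3]))
            for i, r in enumerate(arr)
        ]
        return cls(studies, truth)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log effect and within-study variance."""

    study_id: str
    theta_hat_k: float | None
    var_k: float | None
    included: bool
    corrected: bool


@dataclass
class MethodResult:
    """A single method's pooled result on the log-effect scale."""

    method: str
    measure: Measure
    est: float = math.nan
    se: float = math.nan
    ci_lo: float = math.nan
    ci_hi: float = math.nan
    df: float | None = None
    tau2_hat: float | None = None
    converged: bool = False
    n_studies_used: int = 0
    loglik: float | None = None

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "measure": self.measure.value,
            "est": self.est,
            "se": self.se,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "df": self.df,
            "tau2_hat": self.tau2_hat,
            "converged": self.converged,
            "n_studies_used": self.n_studies_used,
        }
        return d


def _coerce_dataset(X) -> MetaDataset:
    """Accept a MetaDataset, a (K,4) array, or a DataFrame with the CSV schema."""
    if isinstance(X, MetaDataset):
        return X
    if isinstance(X, pd.DataFrame):
        cols = ["y_t", "n_t", "y_c", "n_c"]
        if all(c in X.columns for c in cols):
            studies = [
                StudyRecord(
                    str(row.get("study_id", i + 1)),
                    int(row["y_t"]),
                    int(row["n_t"]),
                    int(row["y_c"]),
                    int(row["n_c"]),
                )
                for i, (_, row) in enumerate(X.iterrows())
            ]
            return MetaDataset(studies)
        raise ValueError(f"DataFrame must have columns {cols}")
    return MetaDataset.from_counts(np.asarray(X, dtype=float))


def validate_dataset(dataset: MetaDataset) -> MetaDataset:
    """Check all study invariants, returning the dataset unchanged if valid.

    Raises ``ValueError`` naming the first violated invariant.
    """
    if dataset.k < 1:
        raise ValueError("K must be >= 1 (empty study list)")
    seen: set[str] = set()
    for s in dataset.studies:
        if s.study_id in seen:
            raise ValueError(f"duplicate study_id {s.study_id!r}")
        seen.add(s.study_id)
        if s.n_t < 1 or s.n_c < 1:
            raise ValueError(f"study {s.study_id}: empty arm (n_t={s.n_t}, n_c={s.n_c})")
        if s.y_t < 0 or s.y_c < 0:
            raise ValueError(f"study {s.study_id}: negative event count")
        if s.y_t > s.n_t or s.y_c > s.n_c:
            raise ValueError(f"study {s.study_id}: events exceed arm size")
    return dataset


def classify_zero_studies(dataset: MetaDataset) -> list[ZeroClass]:
    """Label each study none / single_zero / double_zero by its zero-event arms."""
    labels = []
    for s in dataset.studies:
        zt, zc = s.y_t == 0, s.y_c == 0
        if zt and zc:
            labels.append(ZeroClass.DOUBLE_ZERO)
        elif zt or zc:
            labels.append(ZeroClass.SINGLE_ZERO)
        else:
            labels.append(ZeroClass.NONE)
    return labels


def _log_effect(a: float, b: float, c: float, d: float, measure: Measure):
    """Log effect and delta-method variance from cells a=y_t, b=n_t-y_t, c=y_c, d=n_c-y_c."""
    n_t, n_c = a + b, c + d
    if measure == Measure.OR:
        theta = math.log((a * d) / (b * c))
        var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    else:
        theta = math.log((a / n_t) / (c / n_c))
        var = 1.0 / a - 1.0 / n_t + 1.0 / c - 1.0 / n_c
    return theta, var


def per_study_log_effects(
    dataset: MetaDataset,
    measure: Measure | str = Measure.OR,
    policy: str = "ivrem",
) -> list[EffectEstimate]:
    """Per-study log OR / log RR with the inverse-variance continuity policy.

    policy "ivrem": studies with a zero cell (which includes single-zero
    studies) get 0.5 added to all four cells; double-zero studies are excluded.
    policy "none": any study with a zero cell is excluded (the Mantel-Haenszel
    convention used here).
    """
    measure = Measure(measure)
    if policy not in ("ivrem", "none"):
        raise ValueError(f"unknown policy {policy!r}")
    out: list[EffectEstimate] = []
    for s, z in zip(dataset.studies, classify_zero_studies(dataset)):
        a, b = float(s.y_t), float(s.n_t - s.y_t)
        c, d = float(s.y_c), float(s.n_c - s.y_c)
        has_zero_cell = min(a, b, c, d) == 0.0
        if policy == "none":
            if has_zero_cell:
                out.append(EffectEstimate(s.study_id, None, None, False, False))
                continue
            theta, var = _log_effect(a, b, c, d, measure)
            out.append(EffectEstimate(s.study_id, theta, var, True, False))
            continue
        # ivrem policy
        if z == ZeroClass.DOUBLE_ZERO:
            out.append(EffectEstimate(s.study_id, None, None, False, False))
            continue
        corrected = False
        if has_zero_cell:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        theta, var = _log_effect(a, b, c, d, measure)
        out.append(EffectEstimate(s.study_id, theta, var, True, corrected))
    if not any(e.included for e in out):
        raise ValueError("no estimable studies (all excluded by the zero-study policy)")
    return out


# ---------------------------------------------------------------------------
# CSV interfaces

CSV_COLUMNS = ["study_id", "y_t", "n_t", "y_c", "n_c"]


def read_dataset_csv(path) -> MetaDataset:
    """Read a study table CSV with header study_id,y_t,n_t,y_c,n_c."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing columns: {missing}")
    studies = []
    for i, row in df.iterrows():
        try:
            studies.append(
                StudyRecord(
                    str(row["study_id"]),
                    int(row["y_t"]),
                    int(row["n_t"]),
                    int(row["y_c"]),
                    int(row["n_c"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i + 2}: cannot parse counts ({exc})") from exc
    return validate_dataset(MetaDataset(studies))


def results_to_frame(results: Iterable[MethodResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.as_dict()
        scale = "or" if r.measure == Measure.OR else "rr"
        d[scale] = math.exp(r.est) if math.isfinite(r.est) else math.nan
        d["ci_lo_exp"] = math.exp(r.ci_lo) if math.isfinite(r.ci_lo) else math.nan
        d["ci_hi_exp"] = math.exp(r.ci_hi) if math.isfinite(r.ci_hi) else math.nan
        rows.append(d)
    return pd.DataFrame(rows)


def write_results_csv(results: Iterable[MethodResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False, float_format="%.6g")
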