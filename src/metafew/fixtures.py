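"""Bundled toy datasets used across tests, examples, and the CLI.

All fixtures are generated programmatically; ``write_fixtures`` dumps them
as CSV for command-line use.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import CSV_COLUMNS, MetaDataset, StudyRecord

__all__ = ["toy_k2", "toy_k3", "single_zero_set", "double_zero_set", "simpson_set",
           "bbst_recovery_set", "all_fixtures", "write_fixtures"]


def toy_k2() -> MetaDataset:
    """Two small studies with a moderate harmful effect."""
    return MetaDataset([
        StudyRecord("1", 3, 10, 1, 10),
        StudyRecord("2", 4, 12, 2, 12),
    ])


def toy_k3() -> MetaDataset:
    return MetaDataset([
        StudyRecord("1", 10, 20, 5, 20),
        StudyRecord("2", 8, 25, 6, 25),
        StudyRecord("3", 4, 15, 5, 15),
    ])


def single_zero_set() -> MetaDataset:
    """Three studies, one with zero events in the treatment arm."""
    return MetaDataset([
        StudyRecord("1", 0, 10, 3, 10),
        StudyRecord("2", 2, 15, 4, 15),
        StudyRecord("3", 5, 30, 6, 30),
    ])


def double_zero_set() -> MetaDataset:
    """Three studies including one double-zero study."""
    return MetaDataset([
        StudyRecord("1", 0, 10, 0, 20),
        StudyRecord("2", 2, 15, 4, 15),
        StudyRecord("3", 5, 30, 6, 30),
    ])


def simpson_set() -> MetaDataset:
    """Strata with opposing allocation so the collapsed odds ratio flips sign
    against the stratified Mantel-Haenszel odds ratio."""
    return MetaDataset([
        StudyRecord("1", 12, 100, 3, 30),   # low-risk stratum, mostly treated
        StudyRecord("2", 19, 30, 60, 100),  # high-risk stratum, mostly control
    ])


def bbst_recovery_set(seed: int = 7, k: int = 50, n_per_arm: int = 2000,
                      b0: float = -1.5, b_t: float = -0.5, rho: float = 0.05) -> MetaDataset:
    """Data generated from the common-rho beta-binomial model itself."""
    rng = np.random.default_rng(seed)
    f = (1.0 - rho) / rho
    mu_c = 1.0 / (1.0 + np.exp(-b0))
    mu_t = 1.0 / (1.0 + np.exp(-(b0 + b_t)))
    studies = []
    for i in range(k):
        pi_c = rng.beta(mu_c * f, (1 - mu_c) * f)
        pi_t = rng.beta(mu_t * f, (1 - mu_t) * f)
        studies.append(StudyRecord(
            str(i + 1),
            int(rng.binomial(n_per_arm, pi_t)), n_per_arm,
            int(rng.binomial(n_per_arm, pi_c)), n_per_arm,
        ))
    return MetaDataset(studies)


def all_fixtures(seed: int = 7) -> dict[str, MetaDataset]:
    return {
        "toy_k2": toy_k2(),
        "toy_k3": toy_k3(),
        "single_zero": single_zero_set(),
        "double_zero": double_zero_set(),
        "simpson": simpson_set(),
        "bbst_recovery": bbst_recovery_set(seed=seed),
    }


def write_fixtures(outdir, seed: int = 7) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, ds in all_fixtures(seed=seed).items():
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(",".join(CSV_COLUMNS) + "\n")
            for s in ds.studies:
                fh.write(f"{s.study_id},{s.y_t},{s.n_t},{s.y_c},{s.n_c}\n")
        paths.append(path)
    return paths
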