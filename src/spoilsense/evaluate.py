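"""Data-splitting schemes and predicted-vs-actual regression metrics.

Model performance is summarized the way shelf-life studies report it: an
ordinary least-squares fit of predicted on actual TVC, ``predicted =
alpha * actual + beta``, its R^2, and the RMSE of the raw predictions
against the identity line.  Keeping RMSE independent of the fitted line
separates calibration bias (alpha, beta) from prediction error: a model
that is uniformly 1 log too high still has R^2 = 1 but RMSE = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SplitPlan

__all__ = [
    "RegressionFit",
    "random_split",
    "year_holdout_split",
    "evaluate_predictions",
    "build_report",
]


@dataclass(frozen=True)
class RegressionFit:
    """One report row: slope, offset, R^2 and RMSE of predicted vs actual."""

    alpha: float
    beta: float
    r_squared: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 points")
        if self.rmse < 0 or self.r_squared > 1 + 1e-12:
            raise ValueError("invalid fit metrics")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _records_of(dataset):
    """Accept a SpectralDataset/FeatureTable or a plain list of SampleRecord."""
    return list(dataset) if isinstance(dataset, (list, tuple)) else list(dataset.records)


def random_split(dataset, test_count: int | None = None,
                 test_fraction: float | None = None, seed: int = 0) -> SplitPlan:
    """Uniform random train/test split of sample ids, deterministic per seed."""
    ids = [r.sample_id for r in _records_of(dataset)]
    n = len(ids)
    if (test_count is None) == (test_fraction is None):
        raise ValueError("give exactly one of test_count or test_fraction")
    if test_count is None:
        test_count = _round_half_up(test_fraction * n)
    if not 0 < test_count < n:
        raise ValueError(f"test size must be in (0, {n}), got {test_count}")
    rng = np.random.default_rng(seed)
    test = rng.choice(n, size=test_count, replace=False)
    test_ids = frozenset(ids[i] for i in test)
    train_ids = frozenset(ids) - test_ids
    return SplitPlan(train_ids, test_ids, "random", seed)


def year_holdout_split(dataset, held_years, extra_test_count: int = 0,
                       seed: int = 0) -> SplitPlan:
    """External validation split: entire harvest years held out of training.

    The test set is every sample from ``held_years`` plus
    ``extra_test_count`` randomly chosen samples from the remaining years;
    the rest trains.
    """
    held = set(held_years)
    records = _records_of(dataset)
    ids = [r.sample_id for r in records]
    years = {r.sample_id: r.harvest_year for r in records}
    present = {years[s] for s in ids}
    missing_years = held - present
    if missing_years:
        raise ValueError(f"held years not present in dataset: {sorted(missing_years)}")
    held_ids = [s for s in ids if years[s] in held]
    rest = [s for s in ids if years[s] not in held]
    if extra_test_count >= len(rest):
        raise ValueError("extra_test_count leaves no training samples")
    rng = np.random.default_rng(seed)
    extra = list(rng.choice(len(rest), size=extra_test_count, replace=False)) \
        if extra_test_count else []
    extra_ids = {rest[i] for i in extra}
    test_ids = frozenset(held_ids) | frozenset(extra_ids)
    train_ids = frozenset(rest) - frozenset(extra_ids)
    if not train_ids:
        raise ValueError("held years cover the whole dataset; no training samples left")
    return SplitPlan(train_ids, test_ids, "year_holdout", seed)


def evaluate_predictions(actual, predicted) -> RegressionFit:
    """OLS of predicted on actual (alpha, beta, R^2) plus identity-line RMSE."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(a) == 0:
        raise ValueError("constant actual values: regression undefined")
    fit = stats.linregress(a, p)
    rmse = float(np.sqrt(np.mean((p - a) ** 2)))
    return RegressionFit(
        alpha=float(fit.slope),
        beta=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse=rmse,
        n=int(a.size),
    )


def build_report(results: dict) -> pd.DataFrame:
    """Assemble the report table: one row per (dataset, phase).

    ``results`` maps dataset label -> ordered dict of phase label ->
    (actual, predicted) pairs; phases follow the study layout
    ("Cross validation", "Validation A", "Validation B", ...).
    """
    rows = []
    for dataset_label, phases in results.items():
        for phase_label, (actual, predicted) in phases.items():
            fit = evaluate_predictions(actual, predicted)
            rows.append(
                {
                    "dataset": dataset_label,
                    "phase": phase_label,
                    "alpha": fit.alpha,
                    "beta": fit.beta,
                    "r_squared": fit.r_squared,
                    "rmse": fit.rmse,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows, columns=["dataset", "phase", "alpha", "beta",
                                       "r_squared", "rmse", "n"])


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of the report table."""
    lines = []
    for dataset_label, block in report.groupby("dataset", sort=False):
        lines.append(dataset_label)
        lines.append(f"{'':18s}{'alpha':>8s}{'beta':>8s}{'R^2':>8s}{'RMSE':>8s}{'n':>6s}")
        for _, row in block.iterrows():
            lines.append(
                f"{row['phase']:<18s}{row['alpha']:8.2f}{row['beta']:8.2f}"
                f"{row['r_squared']:8.2f}{row['rmse']:8.2f}{row['n']:6d}"
            )
        lines.append("")
    return "\n".join(lines)
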