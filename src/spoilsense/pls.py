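"""PLS regression with knee-point latent-variable selection under MCCV.

The number of latent variables is chosen from the cumulative
explained-response-variance curve: two straight lines are fitted to the
head and tail of the curve at every candidate breakpoint, the breakpoint
with the smallest total squared error wins, and the rounded abscissa of
the two lines' intersection is the selected component count (the
"knee-point").  Model calibration runs 10-fold cross-validation repeated
over 10 Monte-Carlo repartitions of the training data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted, validate_data

from .datasets import FeatureTable, SpectralDataset
from .preprocess import RNVParams, rnv_normalize, truncate_spectra
from .select import (
    FeatureMask,
    bimodality_filter,
    fit_boosted_ensemble,
    select_features_by_importance,
)

__all__ = [
    "PLSModel",
    "CVResult",
    "KneePLSRegressor",
    "fit_pls",
    "variance_curve",
    "knee_point",
    "mc_cross_validate",
    "pooled_cv_predictions",
    "TrainingConfig",
    "TrainedModel",
    "train_pipeline",
    "predict",
]

KNEE_TOL = 1e-10


def _fit_sklearn_pls(X, y, n_components):
    with warnings.catch_warnings():
        # exact low-rank relations make late NIPALS deflations degenerate;
        # the fitted components up to that point are still what we use
        warnings.simplefilter("ignore", UserWarning)
        return PLSRegression(n_components=n_components, scale=True).fit(X, y)


@dataclass
class PLSModel:
    """A fitted single-response PLS model in original feature space.

    ``predict(X) = X @ coefficients + intercept`` exactly reproduces the
    underlying fit; the centering/scaling applied at fit time is recorded.
    """

    n_components: int
    coefficients: np.ndarray
    intercept: float
    feature_ids: list
    x_mean: np.ndarray
    x_std: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept


def fit_pls(X, y, n_components: int, feature_ids=None) -> PLSModel:
    """Fit single-response PLS (NIPALS) with column centering and scaling.

    With ``n_components`` equal to the rank of the centered X, predictions
    coincide with ordinary least squares on the same data.
    """
    X, y = check_X_y(X, y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    model = _fit_sklearn_pls(X, y, n_components)
    coef = np.asarray(model.coef_).reshape(-1)
    x_mean = np.asarray(model._x_mean, dtype=float)
    # fold the centering into the intercept: predict = X @ coef + b0
    intercept = float(np.asarray(model.intercept_).reshape(-1)[0] - x_mean @ coef)
    return PLSModel(
        n_components=n_components,
        coefficients=coef,
        intercept=intercept,
        feature_ids=list(feature_ids) if feature_ids is not None else list(range(p)),
        x_mean=x_mean.copy(),
        x_std=np.asarray(model._x_std, dtype=float).copy(),
    )


def variance_curve(X, y, max_components: int) -> np.ndarray:
    """Cumulative fraction of centered-y variance explained per component count.

    Entry k-1 equals the training R^2 of a k-component PLS fit.  Computed
    from the nested regressions of y on the (orthogonal) X-score vectors,
    which makes the curve non-decreasing by construction.
    """
    X, y = check_X_y(X, y, dtype=float)
    n, p = X.shape
    if not 1 <= max_components <= min(n - 1, p):
        raise ValueError(f"max_components must be in [1, {min(n - 1, p)}]")
    model = _fit_sklearn_pls(X, y, max_components)
    T = np.asarray(model.x_scores_)
    yc = y - y.mean()
    sstot = float(yc @ yc)
    if sstot == 0:
        raise ValueError("constant response")
    curve = np.empty(max_components)
    for k in range(1, max_components + 1):
        design = np.column_stack([np.ones(n), T[:, :k]])
        resid = yc - design @ np.linalg.lstsq(design, yc, rcond=None)[0]
        curve[k - 1] = 1.0 - float(resid @ resid) / sstot
    return np.clip(curve, 0.0, 1.0)


def knee_point(curve, ks=None, tol: float = KNEE_TOL) -> int:
    """Locate the bend of a saturating curve by two-line fitting.

    For every candidate breakpoint b (interior points), straight lines are
    least-squares fitted to points 1..b and b..K; the b with minimal total
    SSE wins (smallest b on ties) and the rounded abscissa of the two
    lines' intersection, clamped to [first k, last k], is returned.  If a
    single line already fits the whole curve (relative SSE <= tol), there
    is no knee and the largest k is returned.
    """
    v = np.asarray(curve, dtype=float)
    if ks is None:
        ks = np.arange(1, v.size + 1, dtype=float)
    else:
        ks = np.asarray(ks, dtype=float)
    K = v.size
    if K < 4:
        raise ValueError("need at least 4 points to locate a knee")

    def line_sse(idx):
        A = np.column_stack([ks[idx], np.ones(idx.stop - idx.start)])
        beta, *_ = np.linalg.lstsq(A, v[idx], rcond=None)
        r = v[idx] - A @ beta
        return beta, float(r @ r)

    _, sse_single = line_sse(slice(0, K))
    scale = float(np.sum((v - v.mean()) ** 2))
    if scale == 0 or sse_single <= tol * scale:
        return int(ks[-1])

    best = None
    for b in range(1, K - 1):  # breakpoint at position b (0-based), shared point
        bl, sl = line_sse(slice(0, b + 1))
        br, sr = line_sse(slice(b, K))
        sse = sl + sr
        if best is None or sse < best[0]:
            best = (sse, bl, br, b)
    _, (a1, c1), (a2, c2), b = best
    if a1 == a2:  # parallel head/tail lines: the breakpoint itself is the knee
        x = ks[b]
    else:
        x = (c2 - c1) / (a1 - a2)
    k_star = int(np.floor(x + 0.5))  # round half up
    return int(np.clip(k_star, ks[0], ks[-1]))


@dataclass
class CVResult:
    """Monte-Carlo cross-validation record."""

    rmse_grid: np.ndarray  # repartitions x folds x candidate components
    variance_curve: np.ndarray
    selected_components: int
    seed: int
    folds: int
    repartitions: int

    def mean_rmse(self) -> np.ndarray:
        """Mean held-out RMSE per candidate component count."""
        return self.rmse_grid.mean(axis=(0, 1))


def mc_cross_validate(X, y, folds: int = 10, repartitions: int = 10,
                      max_components: int | None = None, seed: int = 0) -> CVResult:
    """k-fold CV repeated over fresh random repartitions, per component count.

    The variance curve (and hence the knee-selected component count) is
    computed on the full data; the RMSE grid records out-of-fold error for
    every repartition, fold and candidate component count.
    """
    X, y = check_X_y(X, y, dtype=float)
    n, p = X.shape
    if n < folds:
        raise ValueError(f"n={n} is smaller than folds={folds}")
    min_fold = n // folds
    min_train = n - (min_fold + 1)
    if min_fold < 2:
        raise ValueError(
            f"a fold would have fewer than 2 samples; use fewer than {folds} folds"
        )
    cap = min(min_train - 1, p)
    if max_components is None:
        max_components = min(15, cap)
    if not 1 <= max_components <= cap:
        raise ValueError(f"max_components must be in [1, {cap}]")

    rng = np.random.default_rng(seed)
    grid = np.empty((repartitions, folds, max_components))
    for r in range(repartitions):
        perm = rng.permutation(n)
        parts = np.array_split(perm, folds)
        for f, test_idx in enumerate(parts):
            train_idx = np.setdiff1d(perm, test_idx)
            for k in range(1, max_components + 1):
                m = fit_pls(X[train_idx], y[train_idx], k)
                err = m.predict(X[test_idx]) - y[test_idx]
                grid[r, f, k - 1] = float(np.sqrt(np.mean(err**2)))
    curve = variance_curve(X, y, max_components)
    k_sel = knee_point(curve) if max_components >= 4 else int(
        np.argmin(grid.mean(axis=(0, 1))) + 1
    )
    return CVResult(grid, curve, k_sel, seed, folds, repartitions)


def pooled_cv_predictions(X, y, n_components: int, folds: int = 10,
                          repartitions: int = 10, seed: int = 0):
    """Pooled out-of-fold predictions across all Monte-Carlo repartitions.

    Returns (actual, predicted) with one entry per sample per repartition —
    the inputs of a "Cross validation" report row.
    """
    X, y = check_X_y(X, y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    actual, predicted = [], []
    for _ in range(repartitions):
        perm = rng.permutation(n)
        for test_idx in np.array_split(perm, folds):
            train_idx = np.setdiff1d(perm, test_idx)
            m = fit_pls(X[train_idx], y[train_idx], n_components)
            actual.append(y[test_idx])
            predicted.append(m.predict(X[test_idx]))
    return np.concatenate(actual), np.concatenate(predicted)


class KneePLSRegressor(RegressorMixin, BaseEstimator):
    """PLS regressor whose component count is chosen by the knee-point rule.

    With ``n_components="knee"`` (default), fit runs Monte-Carlo
    cross-validation and the knee-point of the explained-variance curve;
    an integer fixes the count directly.  Fitted attributes:
    ``n_components_``, ``coef_``, ``intercept_``, ``cv_result_``.
    """

    def __init__(self, n_components="knee", max_components: int | None = None,
                 folds: int = 10, repartitions: int = 10, random_state: int = 0):
        self.n_components = n_components
        self.max_components = max_components
        self.folds = folds
        self.repartitions = repartitions
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float, y_numeric=True)
        n, p = X.shape
        if n < 2:
            raise ValueError(f"n_samples = {n}: need at least 2 samples")
        if self.n_components == "knee":
            min_train = n - (n // self.folds + 1)
            cap = max(min(min_train - 1, p), 1)
            max_k = cap if self.max_components is None else min(self.max_components, cap)
            self.cv_result_ = mc_cross_validate(
                X, y, folds=self.folds, repartitions=self.repartitions,
                max_components=max_k, seed=self.random_state,
            )
            k = self.cv_result_.selected_components
        else:
            k = int(self.n_components)
            self.cv_result_ = None
        self.model_ = fit_pls(X, y, k)
        self.n_components_ = k
        self.coef_ = self.model_.coefficients
        self.intercept_ = self.model_.intercept
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, dtype=float, reset=False)
        return self.model_.predict(X)


# ---------------------------------------------------------------------------
# End-to-end training


@dataclass(frozen=True)
class TrainingConfig:
    """Configuration of the end-to-end sensor pipeline."""

    sensor: str = "ftir"  # ftir | msi | enose
    truncate_low: float = 900.0
    truncate_high: float = 2700.0
    rnv_mode: str = "per_spectrum"
    rnv_epsilon: float = 1e-12
    selection_rule: str = "threshold_mean"  # or top_k
    top_k: int | None = None
    cycles: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    folds: int = 10
    repartitions: int = 10
    max_components: int = 15
    selection_curve: str = "variance"  # or "cv_rmse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor not in ("ftir", "msi", "enose"):
            raise ValueError("sensor must be ftir, msi or enose")
        if self.selection_curve not in ("variance", "cv_rmse"):
            raise ValueError("selection_curve must be 'variance' or 'cv_rmse'")


@dataclass
class TrainedModel:
    """Everything needed to replay the pipeline on new data."""

    config: TrainingConfig
    mask: FeatureMask
    pls: PLSModel
    cv: CVResult

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "config": asdict(self.config),
            "mask": {
                "selected": list(self.mask.selected),
                "scores": {str(k): v for k, v in self.mask.scores.items()},
                "rule": self.mask.rule,
            },
            "pls": {
                "n_components": self.pls.n_components,
                "coefficients": self.pls.coefficients.tolist(),
                "intercept": self.pls.intercept,
                "feature_ids": list(self.pls.feature_ids),
                "x_mean": self.pls.x_mean.tolist(),
                "x_std": self.pls.x_std.tolist(),
            },
            "cv": {
                "rmse_grid": self.cv.rmse_grid.tolist(),
                "variance_curve": self.cv.variance_curve.tolist(),
                "selected_components": self.cv.selected_components,
                "seed": self.cv.seed,
                "folds": self.cv.folds,
                "repartitions": self.cv.repartitions,
            },
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        config = TrainingConfig(**doc["config"])
        raw_sel = doc["mask"]["selected"]
        selected = tuple(raw_sel)
        scores = doc["mask"]["scores"]
        mask = FeatureMask(selected, scores, doc["mask"]["rule"])
        p = doc["pls"]
        pls = PLSModel(
            n_components=p["n_components"],
            coefficients=np.array(p["coefficients"]),
            intercept=p["intercept"],
            feature_ids=p["feature_ids"],
            x_mean=np.array(p["x_mean"]),
            x_std=np.array(p["x_std"]),
        )
        c = doc["cv"]
        cv = CVResult(np.array(c["rmse_grid"]), np.array(c["variance_curve"]),
                      c["selected_components"], c["seed"], c["folds"], c["repartitions"])
        return cls(config, mask, pls, cv)


def _preprocess(dataset, config: TrainingConfig):
    """Truncation (FT-IR) + RNV; returns (matrix, feature ids)."""
    rnv = RNVParams(config.rnv_mode, config.rnv_epsilon)
    if isinstance(dataset, SpectralDataset):
        if config.sensor == "ftir":
            dataset = truncate_spectra(dataset, config.truncate_low, config.truncate_high)
        dataset = rnv_normalize(dataset, rnv)
        return dataset.absorbance, [float(w) for w in dataset.wavenumbers]
    dataset = rnv_normalize(dataset, rnv)
    return dataset.values, list(dataset.feature_names)


def train_pipeline(dataset, config: TrainingConfig | None = None) -> TrainedModel:
    """Preprocess, select features, calibrate by MCCV and fit the final PLS.

    FT-IR: truncation -> RNV -> boosted-importance selection.
    MSI / e-nose: RNV -> GMM-BIC bimodality filter.
    Then Monte-Carlo cross-validation with knee-point component selection
    and a final PLS refit on all training samples.
    """
    config = config or TrainingConfig()
    y = dataset.tvc()
    X, feature_ids = _preprocess(dataset, config)
    if config.sensor == "ftir":
        imp = fit_boosted_ensemble(
            X, y, cycles=config.cycles, learning_rate=config.learning_rate,
            max_depth=config.max_depth, seed=config.seed,
        )
        mask = select_features_by_importance(
            imp, rule=config.selection_rule, k=config.top_k, feature_ids=feature_ids
        )
    else:
        table = FeatureTable([str(f) for f in feature_ids], X, list(dataset.records))
        mask = bimodality_filter(table, seed=config.seed)
    cols = mask.indices(feature_ids)
    Xs = X[:, cols]
    max_k = min(config.max_components, Xs.shape[1], Xs.shape[0] - 1)
    cv = mc_cross_validate(Xs, y, folds=config.folds, repartitions=config.repartitions,
                           max_components=max_k, seed=config.seed)
    if config.selection_curve == "cv_rmse" and max_k >= 4:
        # knee of the held-out RMSE curve instead of explained variance
        k_sel = knee_point(cv.mean_rmse())
        cv = CVResult(cv.rmse_grid, cv.variance_curve, k_sel, cv.seed,
                      cv.folds, cv.repartitions)
    pls = fit_pls(Xs, y, cv.selected_components,
                  feature_ids=[feature_ids[i] for i in cols])
    return TrainedModel(config, mask, pls, cv)


def predict(model: TrainedModel, dataset) -> np.ndarray:
    """Replay the recorded preprocessing and mask, then apply the PLS model.

    Feature lookup is by value (wavenumber) or name, so column order in the
    incoming dataset is irrelevant; missing required features raise an
    error listing them.
    """
    X, feature_ids = _preprocess(dataset, model.config)
    index = {f: i for i, f in enumerate(feature_ids)}
    missing = [f for f in model.pls.feature_ids if f not in index]
    if missing:
        raise ValueError(f"dataset is missing required features: {missing}")
    cols = [index[f] for f in model.pls.feature_ids]
    return model.pls.predict(X[:, cols])
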