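"""Feature selection: boosted-ensemble importances and GMM-BIC bimodality.

Two mechanisms, matched to the two data regimes in the pipeline:

* High-dimensional FT-IR (1800 wavenumbers, ~100-300 samples): least-squares
  gradient boosting of shallow regression trees ranks wavenumbers by the
  total squared-error reduction their splits achieve; features at or above
  the mean importance (or the top k) are retained — an order-of-magnitude
  reduction without hard-coding a count.

* Low-dimensional MSI / e-nose tables: a per-feature bimodality screen.
  Each feature's values across samples are fitted with a one- and a
  two-component Gaussian mixture; the feature is kept only when the
  two-component model wins by BIC.  A feature that separates fresh from
  spoiled samples is bimodal across a storage trial, while a feature blind
  to microbial load is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .datasets import FeatureTable

__all__ = [
    "FeatureMask",
    "GMMResult",
    "fit_boosted_ensemble",
    "select_features_by_importance",
    "gmm_bic",
    "bimodality_filter",
    "BoostedImportanceSelector",
    "BimodalitySelector",
]


@dataclass(frozen=True)
class FeatureMask:
    """Outcome of a selection step: which features survive, and why."""

    selected: tuple
    scores: dict
    rule: str

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("selection produced an empty feature set")

    def indices(self, universe) -> np.ndarray:
        index = {f: i for i, f in enumerate(universe)}
        missing = [f for f in self.selected if f not in index]
        if missing:
            raise KeyError(f"features not in universe: {missing}")
        return np.array([index[f] for f in self.selected])


# ---------------------------------------------------------------------------
# Boosted-ensemble importances


def fit_boosted_ensemble(X, y, cycles: int = 100, learning_rate: float = 0.1,
                         max_depth: int = 3, subsample: float = 1.0,
                         seed: int = 0) -> np.ndarray:
    """Least-squares gradient boosting importances, normalized to sum 1.

    Importance of a feature is the total squared-error reduction over all
    splits that use it, summed over the ensemble's trees.
    """
    X, y = check_X_y(X, y, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y is constant")
    booster = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=cycles,
        learning_rate=learning_rate,
        max_depth=max_depth,
        subsample=subsample,
        random_state=seed,
    ).fit(X, y)
    # unnormalized impurity reduction per tree, summed across the ensemble
    total = np.zeros(X.shape[1])
    for stage in booster.estimators_:
        total += stage[0].tree_.compute_feature_importances(normalize=False)
    s = total.sum()
    return total / s if s > 0 else total


def select_features_by_importance(importances, rule: str = "threshold_mean",
                                  k: int | None = None,
                                  feature_ids=None) -> FeatureMask:
    """Keep features with importance >= mean (``threshold_mean``) or the top k.

    ``top_k`` ties break towards the lower feature index.
    """
    imp = np.asarray(importances, dtype=float)
    if imp.size == 0:
        raise ValueError("importances must be non-empty")
    ids = list(feature_ids) if feature_ids is not None else list(range(imp.size))
    if len(ids) != imp.size:
        raise ValueError("feature_ids length does not match importances")
    if rule == "threshold_mean":
        keep = np.flatnonzero(imp >= imp.mean())
        desc = "threshold_mean"
    elif rule == "top_k":
        if k is None:
            raise ValueError("top_k rule requires k")
        if k > imp.size:
            raise ValueError(f"k={k} exceeds {imp.size} features")
        order = np.lexsort((np.arange(imp.size), -imp))
        keep = np.sort(order[:k])
        desc = f"top_k(k={k})"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return FeatureMask(
        selected=tuple(ids[i] for i in keep),
        scores={ids[i]: float(imp[i]) for i in range(imp.size)},
        rule=desc,
    )


# ---------------------------------------------------------------------------
# 1-D Gaussian mixtures by EM


@dataclass(frozen=True)
class GMMResult:
    """A fitted 1-D Gaussian mixture with its BIC.

    ``bic = -2 loglik + n_params ln(n)`` with 2 parameters for one
    component (mean, variance) and 5 for two (means, variances, weight).
    """

    k: int
    weights: tuple
    means: tuple
    variances: tuple
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    loglik_trace: tuple = ()

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(v <= 0 for v in self.variances):
            raise ValueError("variances must be > 0")


def _loglik(x: np.ndarray, w, mu, var) -> float:
    dens = np.zeros_like(x)
    for wi, mi, vi in zip(w, mu, var):
        dens += wi * norm.pdf(x, mi, np.sqrt(vi))
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def gmm_bic(values, k: int, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-6, n_restarts: int = 5) -> GMMResult:
    """Fit a k-component (k in {1, 2}) Gaussian mixture by EM and score by BIC.

    k=1 is closed form (ML mean and variance).  k=2 uses EM with a
    quantile-split initialization plus seeded random restarts, a variance
    floor of 1e-9 * var(values), and a log-likelihood tolerance of ``tol``.
    The per-iteration log-likelihood trace of the winning restart is kept
    so monotonicity is checkable.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 values")
    var_x = float(np.var(x))
    if var_x == 0:
        raise ValueError("zero-variance input")
    if k == 1:
        mu = float(np.mean(x))
        ll = _loglik(x, (1.0,), (mu,), (var_x,))
        return GMMResult(1, (1.0,), (mu,), (var_x,), ll,
                         -2.0 * ll + 2.0 * np.log(n), True, 0, (ll,))
    if k != 2:
        raise ValueError("k must be 1 or 2")

    floor = 1e-9 * var_x
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            lo, hi = x[x <= np.median(x)], x[x > np.median(x)]
            if hi.size == 0:  # ties at the median
                lo, hi = np.sort(x)[: n // 2], np.sort(x)[n // 2:]
            mu = np.array([lo.mean(), hi.mean()])
            var = np.maximum(np.array([lo.var(), hi.var()]), floor * 10)
        else:
            q = np.sort(rng.uniform(0.1, 0.9, 2))
            mu = np.quantile(x, q)
            if mu[0] == mu[1]:
                mu = mu + np.array([-0.5, 0.5]) * np.sqrt(var_x)
            var = np.array([var_x, var_x])
        w = np.array([0.5, 0.5])
        trace = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E step
            comp = np.stack([wi * norm.pdf(x, mi, np.sqrt(max(vi, floor)))
                             for wi, mi, vi in zip(w, mu, var)])
            total = np.maximum(comp.sum(axis=0), 1e-300)
            resp = comp / total
            ll = float(np.sum(np.log(total)))
            trace.append(ll)
            if ll - prev < tol and it > 1:
                converged = True
                break
            prev = ll
            # M step
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-12)
            w = nk / n
            mu = (resp @ x) / nk
            var = np.maximum(
                np.array([(resp[c] @ (x - mu[c]) ** 2) / nk[c] for c in range(2)]),
                floor,
            )
        ll = trace[-1]
        if best is None or ll > best[0]:
            best = (ll, w.copy(), mu.copy(), var.copy(), converged, it, tuple(trace))

    ll, w, mu, var, converged, it, trace = best
    order = np.argsort(mu)
    w, mu, var = w[order], mu[order], var[order]
    w = w / w.sum()
    return GMMResult(2, tuple(w), tuple(mu), tuple(var), ll,
                     -2.0 * ll + 5.0 * np.log(n), converged, it, trace)


def bimodality_filter(table: FeatureTable, seed: int = 0) -> FeatureMask:
    """Keep a feature iff a 2-component mixture beats 1 component by BIC.

    Zero-variance features are dropped with a warning, never an error.
    """
    kept = []
    scores = {}
    for j, name in enumerate(table.feature_names):
        v = table.values[:, j]
        if np.var(v) == 0:
            warnings.warn(f"dropping zero-variance feature {name!r}", stacklevel=2)
            continue
        r1 = gmm_bic(v, 1, seed=seed)
        r2 = gmm_bic(v, 2, seed=seed)
        delta = r1.bic - r2.bic  # > 0 means bimodal wins
        scores[name] = float(delta)
        if r2.bic < r1.bic:
            kept.append(name)
    if not kept:
        raise ValueError("no informative features: every feature was unimodal or constant")
    return FeatureMask(tuple(kept), scores, "bimodal_bic")


# ---------------------------------------------------------------------------
# sklearn estimator facades


class BoostedImportanceSelector(SelectorMixin, BaseEstimator):
    """Wavelength selection by gradient-boosted-ensemble importance.

    Fits an LSBoost-style ensemble (squared-error gradient boosting of
    shallow trees) and keeps features whose importance clears the chosen
    rule.  Fitted attributes: ``importances_`` (sums to 1 whenever any
    split occurred) and ``support_``.
    """

    def __init__(self, cycles: int = 100, learning_rate: float = 0.1,
                 max_depth: int = 3, subsample: float = 1.0,
                 rule: str = "threshold_mean", k: int | None = None,
                 random_state: int = 0):
        self.cycles = cycles
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.subsample = subsample
        self.rule = rule
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.importances_ = fit_boosted_ensemble(
            X, y, cycles=self.cycles, learning_rate=self.learning_rate,
            max_depth=self.max_depth, subsample=self.subsample,
            seed=self.random_state,
        )
        mask = select_features_by_importance(self.importances_, rule=self.rule, k=self.k)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[list(mask.selected)] = True
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class BimodalitySelector(SelectorMixin, BaseEstimator):
    """Per-feature 1-vs-2-component Gaussian-mixture BIC screen."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        support = np.zeros(X.shape[1], dtype=bool)
        deltas = np.full(X.shape[1], np.nan)
        for j in range(X.shape[1]):
            v = X[:, j]
            if np.var(v) == 0:
                warnings.warn(f"dropping zero-variance feature {j}", stacklevel=2)
                continue
            r1 = gmm_bic(v, 1, seed=self.random_state)
            r2 = gmm_bic(v, 2, seed=self.random_state)
            deltas[j] = r1.bic - r2.bic
            support[j] = r2.bic < r1.bic
        if not support.any():
            raise ValueError("no informative features: every feature was unimodal or constant")
        self.bic_delta_ = deltas
        self.support_ = support
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
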