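"""Uncertainty-aware conformalized quantile regression with a forest core.

The core regressor is a quantile regression forest (qRF): a random forest
whose leaves retain the raw training targets, so that any conditional
quantile can be read off the Meinshausen weighted empirical CDF — the weight
of training point i at query x is the average over trees of
``1[same leaf]/leaf size``. Leaves are defined over *all* training points
routed through each fitted tree, which makes the CDF deterministic given the
forest and directly checkable by brute force.

Conformalization is uncertainty-aware: nonconformity scores are the raw
quantile residuals scaled by the per-query epistemic spread s(x) (standard
deviation of the per-tree median predictions), so intervals widen where the
ensemble disagrees. With a calibration set of size n the adjustment
``c_hat`` is the ``ceil(level*(n+1))``-th smallest score, giving the usual
finite-sample marginal coverage guarantee at the nominal level. Setting
s(x) ≡ 1 recovers plain conformalized quantile regression (CQR).

Intervals at other levels reuse the stored calibration scores with a
level-dependent rank: the score function is fixed, only the conformal
quantile moves, so the guarantee holds at every requested level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor

SPREAD_EPS = 1e-6  # floor on s(x); avoids division by zero on pure leaves


@dataclass
class QuantileForest:
    """Fitted qRF: sklearn forest plus per-tree leaf membership of training targets."""

    forest: RandomForestRegressor
    y_train: np.ndarray
    train_leaves: np.ndarray  # (n_train, n_trees) leaf id of each training point
    n_trees: int
    leaf_min: int
    rng_seed: int
    # per-tree lookup tables, built at fit time
    _leaf_codes: list = field(default_factory=list, repr=False)  # leaf id -> code
    _leaf_values: list = field(default_factory=list, repr=False)  # code -> sorted targets

    @property
    def n_train(self) -> int:
        return len(self.y_train)


def _as_array(X) -> np.ndarray:
    return np.asarray(getattr(X, "values", X), dtype=float)


def fit_quantile_forest(
    X,
    y,
    n_trees: int = 500,
    leaf_min: int = 5,
    seed: int = 0,
    max_features: Union[int, float, str, None] = 1.0,
) -> QuantileForest:
    """Train a quantile regression forest on bootstrap samples.

    ``X`` may be a FeatureMatrix or array; ``y`` the targets in log10 mol/kg-d.
    Deterministic given ``seed``.
    """
    Xa, ya = _as_array(X), np.asarray(y, dtype=float)
    if Xa.shape[0] != len(ya):
        raise ValueError("X and y must have the same number of rows")
    if len(ya) < 2:
        raise ValueError("need at least 2 training points")
    if len(ya) < leaf_min:
        raise ValueError(f"n={len(ya)} smaller than leaf_min={leaf_min}")
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=leaf_min,
        random_state=seed,
        bootstrap=True,
        max_features=max_features,
        n_jobs=1,
    )
    forest.fit(Xa, ya)
    train_leaves = forest.apply(Xa)
    model = QuantileForest(forest, ya, train_leaves, n_trees, leaf_min, seed)
    for t in range(n_trees):
        leaves_t = train_leaves[:, t]
        uniq, codes = np.unique(leaves_t, return_inverse=True)
        lookup = {leaf: c for c, leaf in enumerate(uniq)}
        values = [np.sort(ya[codes == c]) for c in range(len(uniq))]
        model._leaf_codes.append(lookup)
        model._leaf_values.append(values)
    return model


def _query_codes(model: QuantileForest, X) -> np.ndarray:
    """Per-tree leaf codes for query rows, shape (m, n_trees)."""
    leaves = model.forest.apply(_as_array(X))
    out = np.empty_like(leaves)
    for t in range(model.n_trees):
        lut = model._leaf_codes[t]
        out[:, t] = [lut[leaf] for leaf in leaves[:, t]]
    return out


def meinshausen_weights(model: QuantileForest, X) -> np.ndarray:
    """Weighted-CDF weights, shape (m, n_train); rows sum to 1."""
    q_codes = _query_codes(model, X)
    n, m = model.n_train, q_codes.shape[0]
    W = np.zeros((m, n))
    for t in range(model.n_trees):
        codes_t = np.array(
            [model._leaf_codes[t][leaf] for leaf in model.train_leaves[:, t]]
        )
        sizes = np.bincount(codes_t)
        match = q_codes[:, t][:, None] == codes_t[None, :]
        W += match / sizes[q_codes[:, t]][:, None]
    return W / model.n_trees


def _weighted_quantiles(
    y_sorted: np.ndarray, cumw: np.ndarray, levels: np.ndarray
) -> np.ndarray:
    """Left-continuous inverse of the weighted empirical CDF: inf{y : F(y) >= q}."""
    idx = np.searchsorted(cumw, np.asarray(levels) * cumw[-1] - 1e-12, side="left")
    return y_sorted[np.minimum(idx, len(y_sorted) - 1)]


def _empirical_quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Left-continuous empirical quantile of equally weighted sorted values."""
    k = max(int(math.ceil(q * len(sorted_vals))), 1)
    return float(sorted_vals[k - 1])


def forest_quantiles(
    model: QuantileForest, X, levels: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble and per-tree conditional quantiles.

    Returns ``(ensemble, per_tree)`` with shapes (m, L) and (m, n_trees, L).
    Ensemble quantiles come from the Meinshausen weighted CDF; per-tree
    quantiles from each tree's own leaf values. Both use the left-continuous
    inverse CDF, so estimates are nondecreasing in the level.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    if np.any((levels <= 0) | (levels >= 1)):
        raise ValueError("levels must lie strictly inside (0, 1)")

    order = np.argsort(model.y_train, kind="stable")
    y_sorted = model.y_train[order]
    W = meinshausen_weights(model, X)[:, order]
    cumw = np.cumsum(W, axis=1)
    m = W.shape[0]
    ensemble = np.empty((m, levels.size))
    for i in range(m):
        ensemble[i] = _weighted_quantiles(y_sorted, cumw[i], levels)

    q_codes = _query_codes(model, X)
    per_tree = np.empty((m, model.n_trees, levels.size))
    for t in range(model.n_trees):
        vals = model._leaf_values[t]
        # quantile table per leaf of this tree, computed once
        table = np.array(
            [[_empirical_quantile(v, q) for q in levels] for v in vals]
        )
        per_tree[:, t, :] = table[q_codes[:, t]]
    return ensemble, per_tree


def ensemble_quantiles(model: QuantileForest, X, levels: Sequence[float]) -> np.ndarray:
    """Ensemble quantiles only (skips per-tree tables)."""
    levels = np.asarray(levels, dtype=float)
    order = np.argsort(model.y_train, kind="stable")
    y_sorted = model.y_train[order]
    W = meinshausen_weights(model, X)[:, order]
    cumw = np.cumsum(W, axis=1)
    out = np.empty((W.shape[0], levels.size))
    for i in range(W.shape[0]):
        out[i] = _weighted_quantiles(y_sorted, cumw[i], levels)
    return out


def tree_median_spread(model: QuantileForest, X) -> np.ndarray:
    """Epistemic spread s(x): SD of per-tree median predictions, floored at eps."""
    q_codes = _query_codes(model, X)
    med = np.empty((q_codes.shape[0], model.n_trees))
    for t in range(model.n_trees):
        med_table = np.array(
            [_empirical_quantile(v, 0.5) for v in model._leaf_values[t]]
        )
        med[:, t] = med_table[q_codes[:, t]]
    return np.maximum(med.std(axis=1), SPREAD_EPS)


@dataclass
class ConformalAdjustment:
    """Split-conformal adjustment fitted on a calibration set.

    ``scores`` are the spread-scaled nonconformity scores; ``c_hat`` the
    conformal quantile at the construction level.
    """

    level: float
    c_hat: float
    scores: np.ndarray
    n_cal: int
    spread: str  # "tree_sd" (uncertainty-aware) or "constant" (plain CQR)

    def c_hat_at(self, level: float) -> float:
        """Conformal quantile of the stored scores at another nominal level."""
        k = min(int(math.ceil(level * (self.n_cal + 1))), self.n_cal)
        if k < 1:
            raise ValueError(f"level {level} too low for n_cal={self.n_cal}")
        return float(np.sort(self.scores)[k - 1])


@dataclass
class IntervalPrediction:
    """Median with a two-sided prediction interval at a nominal coverage level.

    ``sigma`` is the per-chemical predictive SD used by the calibration
    diagnostics. If not supplied it defaults to the Gaussian-equivalent SD
    ``width / (2 z_{1-(1-level)/2})`` — the sigma of a normal whose central
    ``level`` interval has this width. Probabilistic models that sample their
    predictive distribution pass the SD of their draws instead.
    """

    chem_id: str
    median: float
    lower: float
    upper: float
    level: float
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.lower <= self.median <= self.upper:
            raise ValueError("interval must satisfy lower <= median <= upper")
        if self.sigma is None:
            z = norm.ppf(1.0 - (1.0 - self.level) / 2.0)
            self.sigma = self.width / (2.0 * z)
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def conformal_calibrate(
    model: QuantileForest,
    X_cal,
    y_cal,
    level: float = 0.95,
    spread: str = "tree_sd",
) -> ConformalAdjustment:
    """Compute spread-scaled nonconformity scores on a held-out calibration set.

    Scores: ``E_i = max((q_lo(x_i) - y_i)/s_i, (y_i - q_hi(x_i))/s_i)`` with
    s the per-tree median SD (or 1 for plain CQR). The calibration set must be
    disjoint from the training set for the coverage guarantee to hold.
    """
    y = np.asarray(y_cal, dtype=float)
    if y.size == 0:
        raise ValueError("calibration set must be non-empty")
    if spread not in ("tree_sd", "constant"):
        raise ValueError(f"unknown spread mode {spread!r}")
    alpha = 1.0 - level
    qlohi = ensemble_quantiles(model, X_cal, [alpha / 2.0, 1.0 - alpha / 2.0])
    s = tree_median_spread(model, X_cal) if spread == "tree_sd" else np.ones(y.size)
    scores = np.maximum((qlohi[:, 0] - y) / s, (y - qlohi[:, 1]) / s)
    adj = ConformalAdjustment(level, 0.0, scores, y.size, spread)
    adj.c_hat = adj.c_hat_at(level)
    return adj


def predict_intervals(
    model: QuantileForest,
    adj: ConformalAdjustment,
    X,
    chem_ids: Optional[Sequence[str]] = None,
    levels: Optional[Sequence[float]] = None,
):
    """Conformalized prediction intervals.

    Returns a list of :class:`IntervalPrediction` at the adjustment's level,
    or a dict level -> list when ``levels`` is given. Lower/upper are the raw
    ensemble quantiles at the construction level moved out (or in, when the
    conformal quantile is negative) by ``c_hat * s(x)``; the median is clipped
    into the interval.
    """
    if adj is None:
        raise ValueError("unfitted conformal adjustment")
    alpha = 1.0 - adj.level
    base = ensemble_quantiles(model, X, [alpha / 2.0, 0.5, 1.0 - alpha / 2.0])
    s = (
        tree_median_spread(model, X)
        if adj.spread == "tree_sd"
        else np.ones(base.shape[0])
    )
    if chem_ids is None:
        chem_ids = list(getattr(X, "chem_ids", [str(i) for i in range(base.shape[0])]))

    def build(level: float) -> list[IntervalPrediction]:
        c = adj.c_hat_at(level)
        preds = []
        for i in range(base.shape[0]):
            lo = base[i, 0] - c * s[i]
            hi = base[i, 2] + c * s[i]
            if lo > hi:  # strongly negative c_hat at very low levels
                lo = hi = (lo + hi) / 2.0
            med = float(np.clip(base[i, 1], lo, hi))
            preds.append(IntervalPrediction(str(chem_ids[i]), med, lo, hi, level))
        return preds

    if levels is None:
        return build(adj.level)
    return {float(lv): build(float(lv)) for lv in levels}
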