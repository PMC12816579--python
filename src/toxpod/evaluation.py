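"""Cross-validation, regression metrics, paired tests and consensus baselines.

Model quality is estimated by repeated, target-stratified k-fold
cross-validation: targets are binned by empirical quantiles and each bin is
dealt round-robin across folds, so every fold sees the full potency range
despite the heavy-tailed POD distribution. Feature preprocessing (and, for
conformal models, the internal calibration split) happens strictly inside
each training fold. Model comparisons use paired t-tests — either classic
per-chemical pairing (df = n-1) or per-repeat scores with the Nadeau-Bengio
variance correction for repeated CV (df = repeats-1). The conventional
consensus baseline averages the best model with every model not
significantly worse than it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import GridSearchCV

from toxpod.bnn import BNNConfig, fit_bnn, sample_predictions, summarize_predictive
from toxpod.descriptors import (
    FeatureMatrix,
    apply_feature_pipeline,
    fit_feature_pipeline,
)
from toxpod.uacqr import (
    IntervalPrediction,
    conformal_calibrate,
    fit_quantile_forest,
    predict_intervals,
)


@dataclass
class CVScheme:
    outer_folds: int = 10
    inner_folds: int = 5
    repeats: int = 1
    n_strat_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_strat_bins < 2:
            raise ValueError("n_strat_bins must be >= 2")


@dataclass
class MetricsReport:
    mae: float
    mdae: float
    rmse: float
    r2: Optional[float]
    r2_adj: Optional[float]
    pearson: Optional[float]
    spearman: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def stratified_fold_assignment(
    y: Sequence[float], k: int, n_bins: int = 10, seed: int = 0
) -> np.ndarray:
    """Target-stratified fold labels in {0..k-1}.

    Targets are cut into ``n_bins`` quantile bins; within each bin items are
    shuffled (seeded) and dealt round-robin to folds. Deterministic given seed.
    """
    ya = np.asarray(y, dtype=float)
    n = ya.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    edges = np.quantile(ya, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, ya, side="left")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    cursor = rng.integers(k)  # rotate the deal across bins
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = (cursor + j) % k
        cursor = (cursor + len(idx)) % k
    return folds


def regression_metrics(
    y: Sequence[float], y_hat: Sequence[float], n_features: Optional[int] = None
) -> MetricsReport:
    """MAE, MdAE, RMSE, (adjusted) R^2 and rank/linear correlations."""
    ya = np.asarray(y, dtype=float)
    ma = np.asarray(y_hat, dtype=float)
    if ya.size == 0 or ya.size != ma.size:
        raise ValueError("y and y_hat must be equal-length and non-empty")
    e = ya - ma
    mae = float(np.mean(np.abs(e)))
    mdae = float(np.median(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    sstot = float(np.sum((ya - ya.mean()) ** 2))
    if sstot == 0.0:
        r2 = r2_adj = pear = spear = None
    else:
        r2 = 1.0 - float(np.sum(e**2)) / sstot
        r2_adj = None
        if n_features is not None and ya.size - n_features - 1 > 0:
            r2_adj = 1.0 - (1.0 - r2) * (ya.size - 1) / (ya.size - n_features - 1)
        if np.std(ma) == 0:
            pear = spear = None
        else:
            pear = float(stats.pearsonr(ya, ma)[0])
            spear = float(stats.spearmanr(ya, ma)[0])
    return MetricsReport(mae, mdae, rmse, r2, r2_adj, pear, spear)


@dataclass
class PairedTestResult:
    t_stat: float
    df: int
    p_value: float
    cohens_d: float
    ci95: tuple
    mean_diff: float
    degenerate: bool = False


def paired_error_test(
    err_a: Sequence[float],
    err_b: Sequence[float],
    mode: str = "per_chemical",
    test_train_ratio: Optional[float] = None,
) -> PairedTestResult:
    """Two-sided paired t-test on error differences (a - b).

    ``per_chemical``: classic paired t on per-unit errors, df = n-1.
    ``repeated_cv_corrected``: inputs are per-repeat scores; the variance is
    inflated by the Nadeau-Bengio factor (1/r + n_test/n_train) to account
    for overlapping training sets, df = repeats-1. For 10-fold CV the ratio
    defaults to 1/9.
    """
    a = np.asarray(err_a, dtype=float)
    b = np.asarray(err_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("err_a and err_b must be equal-length with n >= 2")
    if mode not in ("per_chemical", "repeated_cv_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math_inf_sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
        return PairedTestResult(t, df, p, 0.0, (mean, mean), mean, degenerate=True)
    if mode == "per_chemical":
        se = sd / np.sqrt(n)
    else:
        ratio = 1.0 / 9.0 if test_train_ratio is None else test_train_ratio
        se = sd * np.sqrt(1.0 / n + ratio)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    d_eff = mean / sd
    tcrit = float(stats.t.ppf(0.975, df))
    return PairedTestResult(
        float(t), df, p, float(d_eff), (mean - tcrit * se, mean + tcrit * se), mean
    )


def math_inf_sign(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


# ---------------------------------------------------------------------------
# estimators: one interface over conformal, Bayesian and conventional models
# ---------------------------------------------------------------------------


class PipelineEstimator:
    """Base: fits the descriptor preprocessing pipeline inside fit()."""

    def __init__(self, corr_threshold: float = 0.9):
        self.corr_threshold = corr_threshold
        self.pipeline_ = None

    def _prepare_train(self, X: FeatureMatrix) -> np.ndarray:
        self.pipeline_ = fit_feature_pipeline(X, self.corr_threshold)
        return apply_feature_pipeline(self.pipeline_, X).values

    def _prepare_test(self, X: FeatureMatrix) -> np.ndarray:
        return apply_feature_pipeline(self.pipeline_, X).values

    def pipeline_hash(self) -> str:
        """Digest of the fitted preprocessing state (leakage probe)."""
        h = hashlib.sha256()
        h.update(self.pipeline_.kept_mask.tobytes())
        if self.pipeline_.power is not None:
            h.update(np.ascontiguousarray(self.pipeline_.power.lambdas_).tobytes())
            scaler = self.pipeline_.power._scaler
            h.update(np.ascontiguousarray(scaler.mean_).tobytes())
            h.update(np.ascontiguousarray(scaler.scale_).tobytes())
        return h.hexdigest()


class UACQREstimator(PipelineEstimator):
    """Conformalized qRF with an internal stratified 20% calibration split."""

    def __init__(
        self,
        n_trees: int = 500,
        leaf_min: int = 5,
        level: float = 0.95,
        cal_fraction: float = 0.2,
        spread: str = "tree_sd",
        seed: int = 0,
        corr_threshold: float = 0.9,
    ):
        super().__init__(corr_threshold)
        self.n_trees, self.leaf_min, self.level = n_trees, leaf_min, level
        self.cal_fraction, self.spread, self.seed = cal_fraction, spread, seed
        self.model_ = None
        self.adj_ = None

    def fit(self, X: FeatureMatrix, y):
        Xp = self._prepare_train(X)
        ya = np.asarray(y, dtype=float)
        n_splits = max(int(round(1.0 / self.cal_fraction)), 2)
        folds = stratified_fold_assignment(ya, n_splits, seed=self.seed)
        cal = folds == 0
        self.model_ = fit_quantile_forest(
            Xp[~cal], ya[~cal], self.n_trees, self.leaf_min, seed=self.seed
        )
        self.adj_ = conformal_calibrate(
            self.model_, Xp[cal], ya[cal], self.level, self.spread
        )
        return self

    def predict(self, X: FeatureMatrix) -> list[IntervalPrediction]:
        Xp = self._prepare_test(X)
        return predict_intervals(self.model_, self.adj_, Xp, chem_ids=X.chem_ids)

    def predict_levels(self, X: FeatureMatrix, levels) -> dict:
        Xp = self._prepare_test(X)
        return predict_intervals(
            self.model_, self.adj_, Xp, chem_ids=X.chem_ids, levels=levels
        )


class BNNEstimator(PipelineEstimator):
    """Variational BNN behind the same fit/predict interface."""

    def __init__(self, config: Optional[BNNConfig] = None, corr_threshold: float = 0.9):
        super().__init__(corr_threshold)
        self.config = config or BNNConfig()
        self.post_ = None

    def fit(self, X: FeatureMatrix, y):
        Xp = self._prepare_train(X)
        self.post_ = fit_bnn(Xp, y, self.config)
        return self

    def predict(self, X: FeatureMatrix, level: float = 0.95) -> list[IntervalPrediction]:
        Xp = self._prepare_test(X)
        samples = sample_predictions(
            self.post_, Xp, seed=self.config.seed, chem_ids=X.chem_ids
        )
        return summarize_predictive(samples, level)


class SklearnEstimator(PipelineEstimator):
    """Conventional point-prediction baseline, optionally grid-searched."""

    def __init__(
        self,
        estimator,
        param_grid: Optional[dict] = None,
        inner_folds: int = 5,
        corr_threshold: float = 0.9,
    ):
        super().__init__(corr_threshold)
        self.estimator = estimator
        self.param_grid = param_grid
        self.inner_folds = inner_folds
        self.model_ = None

    def fit(self, X: FeatureMatrix, y):
        Xp = self._prepare_train(X)
        base = clone(self.estimator)
        if self.param_grid:
            search = GridSearchCV(
                base, self.param_grid, cv=self.inner_folds,
                scoring="neg_root_mean_squared_error",
            )
            search.fit(Xp, np.asarray(y, float))
            self.model_ = search.best_estimator_
        else:
            self.model_ = base.fit(Xp, np.asarray(y, float))
        return self

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        return self.model_.predict(self._prepare_test(X))


def baseline_roster(seed: int = 0) -> dict:
    """The conventional comparison models behind the shared interface."""
    from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
    from sklearn.linear_model import LinearRegression
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.svm import SVR

    return {
        "linear": lambda: SklearnEstimator(LinearRegression()),
        "knn": lambda: SklearnEstimator(
            KNeighborsRegressor(), {"n_neighbors": [3, 5, 10]}
        ),
        "svm": lambda: SklearnEstimator(SVR(), {"C": [0.1, 1.0, 10.0]}),
        "random_forest": lambda: SklearnEstimator(
            RandomForestRegressor(n_estimators=300, random_state=seed)
        ),
        "gradient_boosting": lambda: SklearnEstimator(
            HistGradientBoostingRegressor(random_state=seed)
        ),
        "mlp": lambda: SklearnEstimator(
            MLPRegressor(hidden_layer_sizes=(64,), max_iter=500, random_state=seed)
        ),
    }


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    predictions: pd.DataFrame  # chem_id, repeat, fold, y, median, lower, upper
    per_fold: list  # (repeat, fold, MetricsReport)
    pooled: list  # per-repeat MetricsReport
    scheme: CVScheme
    fold_assignment: np.ndarray = field(default=None, repr=False)

    def pooled_metric(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.pooled])


def _medians(preds) -> np.ndarray:
    if isinstance(preds, list) and preds and isinstance(preds[0], IntervalPrediction):
        return np.array([p.median for p in preds])
    return np.asarray(preds, dtype=float)


def run_cross_validation(
    estimator_factory: Callable[[], PipelineEstimator],
    X: FeatureMatrix,
    y: Sequence[float],
    scheme: CVScheme,
) -> CVResult:
    """Repeated stratified k-fold CV with strictly in-fold preprocessing.

    ``estimator_factory`` builds a fresh estimator per fold. Out-of-fold
    predictions cover every chemical exactly once per repeat.
    """
    ya = np.asarray(y, dtype=float)
    rows, per_fold, pooled = [], [], []
    assignments = np.empty((scheme.repeats, ya.size), dtype=int)
    for rep in range(scheme.repeats):
        folds = stratified_fold_assignment(
            ya, scheme.outer_folds, scheme.n_strat_bins, seed=scheme.seed + rep
        )
        assignments[rep] = folds
        oof = np.full(ya.size, np.nan)
        for f in range(scheme.outer_folds):
            test = folds == f
            Xtr = _subset(X, ~test)
            Xte = _subset(X, test)
            try:
                est = estimator_factory()
                est.fit(Xtr, ya[~test])
                preds = est.predict(Xte)
            except Exception as exc:  # noqa: BLE001 - annotate origin and re-raise
                raise RuntimeError(
                    f"estimator failed in repeat {rep}, fold {f}: {exc}"
                ) from exc
            med = _medians(preds)
            oof[test] = med
            has_iv = isinstance(preds, list) and preds and isinstance(
                preds[0], IntervalPrediction
            )
            for j, i in enumerate(np.flatnonzero(test)):
                rows.append(
                    {
                        "chem_id": X.chem_ids[i],
                        "repeat": rep,
                        "fold": f,
                        "y": ya[i],
                        "median": med[j],
                        "lower": preds[j].lower if has_iv else np.nan,
                        "upper": preds[j].upper if has_iv else np.nan,
                        "sigma": preds[j].sigma if has_iv else np.nan,
                    }
                )
            per_fold.append((rep, f, regression_metrics(ya[test], med)))
        pooled.append(regression_metrics(ya, oof))
    return CVResult(pd.DataFrame(rows), per_fold, pooled, scheme, assignments)


def _subset(X: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    idx = np.flatnonzero(mask)
    return FeatureMatrix(
        [X.chem_ids[i] for i in idx], X.kind, X.values[idx], list(X.feature_names)
    )


def build_consensus(
    predictions: dict,
    per_repeat_errors: dict,
    alpha: float = 0.05,
    only_significantly_best: bool = False,
) -> tuple[np.ndarray, list]:
    """Average the top conventional models into a consensus prediction.

    ``predictions``: model name -> aligned out-of-fold medians.
    ``per_repeat_errors``: model name -> per-repeat scores (e.g. RMSE), used
    in corrected paired t-tests against the best (lowest mean score) model.
    Members are the best model plus every model whose difference from it is
    not significant at ``alpha`` (or, with ``only_significantly_best``, only
    models significantly better than all non-members — stricter reading).
    """
    if not predictions:
        raise ValueError("no candidate models")
    names = list(predictions)
    if len(names) == 1:
        return np.asarray(predictions[names[0]], float), names
    mean_err = {m: float(np.mean(per_repeat_errors[m])) for m in names}
    best = min(names, key=mean_err.get)
    members = [best]
    if not only_significantly_best:
        for m in names:
            if m == best:
                continue
            res = paired_error_test(
                per_repeat_errors[m],
                per_repeat_errors[best],
                mode="repeated_cv_corrected",
            )
            if res.p_value >= alpha:
                members.append(m)
    stack = np.vstack([np.asarray(predictions[m], float) for m in members])
    return stack.mean(axis=0), members
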