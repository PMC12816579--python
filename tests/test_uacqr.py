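import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from toxpod.uacqr import (
    IntervalPrediction,
    _weighted_quantiles,
    conformal_calibrate,
    ensemble_quantiles,
    fit_quantile_forest,
    forest_quantiles,
    meinshausen_weights,
    predict_intervals,
    tree_median_spread,
)


def oracle_weighted_cdf_quantile(model, Xq, levels):
    """Brute-force Meinshausen oracle: explicit loops over trees, training
    points and candidate target values; independent of the vectorized path."""
    Xq = np.atleast_2d(Xq)
    leaves_q = model.forest.apply(Xq)
    out = np.empty((Xq.shape[0], len(levels)))
    for i in range(Xq.shape[0]):
        w = np.zeros(model.n_train)
        for t in range(model.n_trees):
            same = model.train_leaves[:, t] == leaves_q[i, t]
            w[same] += 1.0 / same.sum()
        w /= model.n_trees
        for li, q in enumerate(levels):
            for v in np.unique(model.y_train):
                if w[model.y_train <= v].sum() >= q - 1e-12:
                    out[i, li] = v
                    break
    return out


class TestForestQuantiles:
    def test_hand_weighted_cdf_example(self):
        # two leaves {1,3} and {3,5}, each point weight 1/4: q0.5 -> 3
        y_sorted = np.array([1.0, 3.0, 3.0, 5.0])
        cumw = np.cumsum([0.25, 0.25, 0.25, 0.25])
        assert _weighted_quantiles(y_sorted, cumw, np.array([0.5]))[0] == 3.0
        assert _weighted_quantiles(y_sorted, cumw, np.array([0.2]))[0] == 1.0
        assert _weighted_quantiles(y_sorted, cumw, np.array([0.99]))[0] == 5.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        """Exact equality with the weighted-empirical-CDF oracle on small
        random instances (n <= 50, 1-3 trees)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        n_trees = int(rng.integers(1, 4))
        model = fit_quantile_forest(X, y, n_trees=n_trees, leaf_min=2, seed=seed)
        Xq = rng.normal(size=(5, 2))
        levels = [0.025, 0.25, 0.5, 0.75, 0.975]
        ens, _ = forest_quantiles(model, Xq, levels)
        expected = oracle_weighted_cdf_quantile(model, Xq, levels)
        assert np.array_equal(ens, expected)

    def test_monotone_in_level(self):
        rng = np.random.default_rng(1)
        model = fit_quantile_forest(
            rng.normal(size=(100, 2)), rng.normal(size=100), n_trees=20, seed=1
        )
        ens, per_tree = forest_quantiles(
            model, rng.normal(size=(10, 2)), [0.025, 0.5, 0.975]
        )
        assert (np.diff(ens, axis=1) >= 0).all()
        assert (np.diff(per_tree, axis=2) >= 0).all()

    def test_single_tree_ensemble_equals_tree_quantile(self):
        rng = np.random.default_rng(2)
        model = fit_quantile_forest(
            rng.normal(size=(40, 1)), rng.normal(size=40), n_trees=1, leaf_min=3, seed=2
        )
        ens, per_tree = forest_quantiles(model, rng.normal(size=(6, 1)), [0.25, 0.5])
        assert np.array_equal(ens, per_tree[:, 0, :])

    def test_degenerate_identical_targets(self):
        X = np.array([[0.0], [1.0]] * 5)
        y = np.full(10, 4.2)
        model = fit_quantile_forest(X, y, n_trees=5, leaf_min=1, seed=0)
        ens, _ = forest_quantiles(model, [[0.5]], [0.05, 0.5, 0.95])
        assert (ens == 4.2).all()

    def test_step_function_median(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 200)
        y = (x >= 0).astype(float)
        model = fit_quantile_forest(x[:, None], y, n_trees=50, seed=3)
        ens, _ = forest_quantiles(model, [[-1.0], [1.0]], [0.5])
        assert ens[0, 0] == 0.0 and ens[1, 0] == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(60, 3)), rng.normal(size=60)
        q1 = forest_quantiles(fit_quantile_forest(X, y, 10, seed=9), X[:5], [0.5])[0]
        q2 = forest_quantiles(fit_quantile_forest(X, y, 10, seed=9), X[:5], [0.5])[0]
        assert np.array_equal(q1, q2)

    def test_empty_levels_rejected(self):
        rng = np.random.default_rng(5)
        model = fit_quantile_forest(rng.normal(size=(20, 1)), rng.normal(size=20), 3, 2, 0)
        with pytest.raises(ValueError):
            forest_quantiles(model, [[0.0]], [])

    def test_weights_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        model = fit_quantile_forest(rng.normal(size=(30, 2)), rng.normal(size=30), 7, 2, 1)
        W = meinshausen_weights(model, rng.normal(size=(4, 2)))
        assert np.allclose(W.sum(axis=1), 1.0)


class TestConformal:
    def test_rank_formula_n19(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 1))
        y = rng.normal(size=60)
        model = fit_quantile_forest(X, y, n_trees=10, seed=0)
        Xc, yc = rng.normal(size=(19, 1)), rng.normal(size=19)
        adj = conformal_calibrate(model, Xc, yc, level=0.95)
        # k = ceil(0.95 * 20) = 19 -> c_hat is the maximum score
        assert adj.c_hat == np.max(adj.scores)

    def test_constant_spread_reduces_to_cqr(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(80, 1)), rng.normal(size=80)
        model = fit_quantile_forest(X, y, n_trees=10, seed=1)
        Xc, yc = rng.normal(size=(40, 1)), rng.normal(size=40)
        adj = conformal_calibrate(model, Xc, yc, spread="constant")
        qlohi = ensemble_quantiles(model, Xc, [0.025, 0.975])
        raw = np.maximum(qlohi[:, 0] - yc, yc - qlohi[:, 1])
        assert np.allclose(adj.scores, raw)

    def test_empty_calibration_set_rejected(self):
        rng = np.random.default_rng(2)
        model = fit_quantile_forest(rng.normal(size=(20, 1)), rng.normal(size=20), 3, 2, 0)
        with pytest.raises(ValueError):
            conformal_calibrate(model, np.empty((0, 1)), [])

    def test_zero_adjustment_equals_raw_quantiles(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(80, 1)), rng.normal(size=80)
        model = fit_quantile_forest(X, y, n_trees=10, seed=3)
        adj = conformal_calibrate(model, rng.normal(size=(30, 1)), rng.normal(size=30))
        adj.scores = np.zeros_like(adj.scores)
        adj.c_hat = 0.0
        Xq = rng.normal(size=(5, 1))
        preds = predict_intervals(model, adj, Xq)
        raw = ensemble_quantiles(model, Xq, [0.025, 0.975])
        assert np.allclose([p.lower for p in preds], raw[:, 0])
        assert np.allclose([p.upper for p in preds], raw[:, 1])

    def test_width_nondecreasing_in_level(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(150, 2)), rng.normal(size=150)
        model = fit_quantile_forest(X, y, n_trees=30, seed=4)
        adj = conformal_calibrate(model, rng.normal(size=(60, 2)), rng.normal(size=60))
        by_level = predict_intervals(
            model, adj, rng.normal(size=(8, 2)), levels=[0.5, 0.8, 0.95]
        )
        widths = np.array(
            [[p.width for p in by_level[lv]] for lv in (0.5, 0.8, 0.95)]
        )
        assert (np.diff(widths, axis=0) >= -1e-12).all()

    def test_interval_ordering_and_sigma(self):
        p = IntervalPrediction("x", 0.0, -1.96, 1.96, 0.95)
        assert p.width == pytest.approx(3.92)
        assert p.sigma == pytest.approx(1.0, abs=1e-3)
        with pytest.raises(ValueError):
            IntervalPrediction("x", 5.0, -1.0, 1.0, 0.95)

    def test_marginal_coverage_expectation(self):
        """Mean coverage over seeds stays at or above the nominal level minus
        Monte-Carlo slack (split-conformal guarantee)."""
        covs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-2, 2, 400)
            y = x + rng.normal(0, 0.2 + 0.3 * np.abs(x))
            model = fit_quantile_forest(x[:150, None], y[:150], n_trees=50, seed=seed)
            adj = conformal_calibrate(model, x[150:250, None], y[150:250])
            preds = predict_intervals(model, adj, x[250:, None])
            covs.append(
                np.mean([p.lower <= yy <= p.upper for p, yy in zip(preds, y[250:])])
            )
        assert np.mean(covs) >= 0.94

    def test_spread_higher_for_unseen_cluster(self):
        """Epistemic spread s(x) is larger for queries from a feature-space
        cluster the forest never saw than for in-distribution queries."""
        from toxpod.synthetic import SyntheticSpec, make_synthetic_qsar

        gaps = []
        for seed in range(5):
            d = make_synthetic_qsar(
                SyntheticSpec(n_chems=700, n_clusters=6, seed=seed)
            )
            held = d.clusters == 5
            X = d.descriptors.values
            idx_in = np.flatnonzero(~held)
            rng = np.random.default_rng(seed)
            rng.shuffle(idx_in)
            tr, te_in = idx_in[:400], idx_in[400:]
            model = fit_quantile_forest(X[tr], d.y[tr], n_trees=100, seed=seed)
            s_in = tree_median_spread(model, X[te_in]).mean()
            s_out = tree_median_spread(model, X[held]).mean()
            gaps.append(s_out - s_in)
        assert np.mean(gaps) > 0
        assert sum(g > 0 for g in gaps) >= 4
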