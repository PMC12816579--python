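import numpy as np
import pytest
from scipy import stats

from toxpod.descriptors import FeatureMatrix
from toxpod.evaluation import (
    CVScheme,
    SklearnEstimator,
    UACQREstimator,
    build_consensus,
    paired_error_test,
    regression_metrics,
    run_cross_validation,
    stratified_fold_assignment,
)


def naive_metrics(y, y_hat):
    """Independent elementwise reimplementation of the regression metrics."""
    y, y_hat = list(map(float, y)), list(map(float, y_hat))
    n = len(y)
    errs = sorted(abs(a - b) for a, b in zip(y, y_hat))
    mae = sum(errs) / n
    mdae = errs[n // 2] if n % 2 else (errs[n // 2 - 1] + errs[n // 2]) / 2
    rmse = (sum((a - b) ** 2 for a, b in zip(y, y_hat)) / n) ** 0.5
    ybar = sum(y) / n
    sstot = sum((a - ybar) ** 2 for a in y)
    r2 = 1 - sum((a - b) ** 2 for a, b in zip(y, y_hat)) / sstot
    return mae, mdae, rmse, r2


def _fm(x, kind="morgan_fp"):
    x = np.asarray(x, float)
    return FeatureMatrix(
        [f"c{i}" for i in range(x.shape[0])],
        kind,
        x,
        [f"f{j}" for j in range(x.shape[1])],
    )


class TestRegressionMetrics:
    def test_hand_example(self):
        m = regression_metrics([0, 1, 2], [0, 1, 3])
        assert m.mae == pytest.approx(1 / 3)
        assert m.mdae == pytest.approx(0.0)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.r2 == pytest.approx(0.5)

    def test_identity_and_null_model(self):
        y = np.array([1.0, 2.0, 4.0])
        perfect = regression_metrics(y, y)
        assert perfect.mae == 0 and perfect.rmse == 0 and perfect.r2 == 1
        null = regression_metrics(y, np.full(3, y.mean()))
        assert null.r2 == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 1000))
        y = rng.normal(size=n)
        y_hat = y + rng.normal(0, 0.5, n)
        m = regression_metrics(y, y_hat)
        mae, mdae, rmse, r2 = naive_metrics(y, y_hat)
        assert m.mae == pytest.approx(mae, abs=1e-10)
        assert m.mdae == pytest.approx(mdae, abs=1e-10)
        assert m.rmse == pytest.approx(rmse, abs=1e-10)
        assert m.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_targets_flagged(self):
        m = regression_metrics([1.0, 1.0], [0.5, 1.5])
        assert m.r2 is None


class TestStratifiedFolds:
    def test_sizes_and_determinism(self):
        rng = np.random.default_rng(0)
        y = rng.lognormal(size=100)
        f1 = stratified_fold_assignment(y, 10, seed=1)
        f2 = stratified_fold_assignment(y, 10, seed=1)
        assert np.array_equal(f1, f2)
        assert np.bincount(f1, minlength=10).tolist() == [10] * 10

    def test_stratification_balances_fold_means(self):
        rng = np.random.default_rng(1)
        y = rng.lognormal(1.0, 1.0, 1000)
        folds = stratified_fold_assignment(y, 10, seed=2)
        for f in range(10):
            assert abs(y[folds == f].mean() - y.mean()) < 0.5 * y.std()

    def test_k_exceeds_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_fold_assignment([1.0, 2.0], 3)


class TestPairedErrorTest:
    def test_identical_errors(self):
        r = paired_error_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_stat == 0.0 and r.p_value == 1.0 and r.cohens_d == 0.0
        assert r.degenerate

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(10), rng.random(10)
        r1 = paired_error_test(a, b)
        r2 = paired_error_test(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_hand_example_diffs_123(self):
        """diffs (1,2,3): mean 2, SD 1, t = 2 sqrt(3) ~ 3.464, df = 2."""
        r = paired_error_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.t_stat == pytest.approx(2 * np.sqrt(3), abs=1e-3)
        assert r.df == 2
        assert r.p_value == pytest.approx(
            2 * stats.t.sf(2 * np.sqrt(3), 2), abs=1e-12
        )

    def test_corrected_mode_inflates_variance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.1, 10)
        b = rng.normal(0.9, 0.1, 10)
        classic = paired_error_test(a, b, mode="per_chemical")
        corrected = paired_error_test(a, b, mode="repeated_cv_corrected")
        assert abs(corrected.t_stat) < abs(classic.t_stat)
        assert corrected.df == 9


class TestCrossValidation:
    def test_constant_target_zero_rmse(self):
        rng = np.random.default_rng(4)
        X = _fm((rng.random((40, 6)) < 0.5).astype(float))
        y = np.full(40, 2.5)
        from sklearn.dummy import DummyRegressor

        res = run_cross_validation(
            lambda: SklearnEstimator(DummyRegressor()),
            X,
            y,
            CVScheme(outer_folds=4, n_strat_bins=2),
        )
        assert res.pooled[0].rmse == pytest.approx(0.0)

    def test_out_of_fold_partition(self):
        rng = np.random.default_rng(5)
        X = _fm((rng.random((60, 8)) < 0.5).astype(float))
        y = rng.normal(size=60)
        from sklearn.linear_model import LinearRegression

        res = run_cross_validation(
            lambda: SklearnEstimator(LinearRegression()),
            X,
            y,
            CVScheme(outer_folds=5, repeats=2, seed=1),
        )
        for rep in (0, 1):
            sub = res.predictions[res.predictions["repeat"] == rep]
            assert sorted(sub["chem_id"]) == sorted(X.chem_ids)
            assert len(sub) == 60

    def test_leakage_probe_pipeline_hash(self):
        """Corrupting test-fold targets cannot change the fitted pipeline;
        different training folds give different preprocessing parameters."""
        rng = np.random.default_rng(6)
        x = rng.lognormal(size=(80, 5))
        y = rng.normal(size=80)
        folds = stratified_fold_assignment(y, 4, seed=0)
        hashes = []
        for f in range(4):
            tr = folds != f
            est = UACQREstimator(n_trees=10, seed=0)
            est.fit(_fm(x[tr], "physchem_2d"), y[tr])
            h_clean = est.pipeline_hash()
            y_corrupt = y.copy()
            y_corrupt[~tr] += 100.0  # corrupt only test-fold targets
            est2 = UACQREstimator(n_trees=10, seed=0)
            est2.fit(_fm(x[tr], "physchem_2d"), y_corrupt[tr])
            assert est2.pipeline_hash() == h_clean
            hashes.append(h_clean)
        assert len(set(hashes)) == 4

    def test_estimator_failure_names_fold(self):
        class Boom:
            def fit(self, X, y):
                raise RuntimeError("boom")

        X = _fm(np.random.default_rng(7).random((20, 3)), "physchem_2d")
        with pytest.raises(RuntimeError, match="repeat 0, fold 0"):
            run_cross_validation(
                Boom, X, np.random.default_rng(7).normal(size=20),
                CVScheme(outer_folds=2, n_strat_bins=2),
            )

    def test_interval_model_cv_records_bounds(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(80, 3))
        y = x[:, 0] + rng.normal(0, 0.2, 80)
        res = run_cross_validation(
            lambda: UACQREstimator(n_trees=20, seed=0),
            _fm(x, "physchem_2d"),
            y,
            CVScheme(outer_folds=4, n_strat_bins=4),
        )
        df = res.predictions
        assert (df["lower"] <= df["median"]).all()
        assert (df["median"] <= df["upper"]).all()


class TestConsensus:
    def test_single_candidate_identity(self):
        pred, members = build_consensus({"a": [1.0, 2.0]}, {"a": [0.5]})
        assert members == ["a"] and pred.tolist() == [1.0, 2.0]

    def test_identical_models(self):
        p = [1.0, 2.0, 3.0]
        e = [0.5] * 10
        pred, members = build_consensus({"a": p, "b": p}, {"a": e, "b": e})
        assert sorted(members) == ["a", "b"]
        assert pred.tolist() == p

    def test_grossly_worse_model_excluded(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=50)
        preds = {
            "good1": y + rng.normal(0, 0.1, 50),
            "good2": y + rng.normal(0, 0.1, 50),
            "bad": y + rng.normal(0, 3.0, 50),
        }
        errors = {
            "good1": 0.1 + 0.01 * rng.random(10),
            "good2": 0.1 + 0.01 * rng.random(10),
            "bad": 3.0 + 0.1 * rng.random(10),
        }
        _, members = build_consensus(preds, errors)
        assert "bad" not in members and len(members) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_consensus_rmse_not_worse_than_worst_member(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=40)
        preds = {m: y + rng.normal(0, 0.3 + 0.2 * i, 40) for i, m in enumerate("abc")}
        errors = {
            m: [np.sqrt(np.mean((np.asarray(preds[m]) - y) ** 2))] * 10 for m in preds
        }
        cons, members = build_consensus(preds, errors)
        rmse_cons = np.sqrt(np.mean((cons - y) ** 2))
        worst = max(np.sqrt(np.mean((np.asarray(preds[m]) - y) ** 2)) for m in members)
        assert rmse_cons <= worst + 1e-12
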