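"""Unit and property tests for the boosted regression tree core."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metnorm as mn
from metnorm.boosting import fit_tree

from conftest import exhaustive_best_split


class TestBestSplit:
    def test_perfectly_separable_step(self):
        cand = mn.best_split([1, 2, 3, 4], [0, 0, 10, 10])
        assert cand.cutpoint == 2.5
        assert cand.rss == 0.0
        assert cand.left_mean == 0.0
        assert cand.right_mean == 10.0

    def test_constant_response_ties_break_to_smallest_cutpoint(self):
        cand = mn.best_split([1, 2, 3, 4], [5, 5, 5, 5])
        assert cand.cutpoint == 1.5

    def test_all_x_identical_signals_no_split(self):
        assert mn.best_split([3, 3, 3], [1, 2, 3]) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 31)
        x = rng.uniform(0, 10, n)
        r = rng.normal(0, 5, n)
        cand = mn.best_split(x, r)
        s, rss, lm, rm = exhaustive_best_split(x, r)
        assert cand.cutpoint == s
        assert cand.rss == rss
        assert cand.left_mean == lm and cand.right_mean == rm

    def test_oracle_equivalence_many_instances(self):
        """Exact (j, s, rss) agreement over 100 random instances, n <= 50."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(4, 51)
            x = np.round(rng.uniform(0, 5, n), rng.integers(0, 3))
            r = rng.normal(0, 3, n)
            if np.unique(x).size < 2:
                continue
            cand = mn.best_split(x, r)
            s, rss, _, _ = exhaustive_best_split(x, r)
            assert cand.cutpoint == s and cand.rss == rss


class TestFitTree:
    def test_root_splits_on_the_informative_predictor(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=20), np.repeat([0.0, 1.0], 10)])
        y = np.repeat([0.0, 10.0], 10)
        tree = fit_tree(X, y, n_splits=1)
        assert tree.feature[0] == 1

    def test_constant_response_gives_single_leaf(self):
        X = np.arange(10, dtype=float)[:, None]
        tree = fit_tree(X, np.full(10, 7.0), n_splits=3)
        assert tree.n_splits == 0
        assert np.all(tree.feature == -1)
        assert tree.value[0] == 7.0

    def test_leaf_predictions_are_region_means(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        tree = fit_tree(X, y, n_splits=4)
        pred = tree.predict(X)
        for leaf_value in np.unique(pred):
            rows = pred == leaf_value
            assert np.isclose(y[rows].mean(), leaf_value)

    def test_two_splits_beat_every_single_split(self):
        """Depth-2 tree RSS <= RSS of every possible depth-1 tree (oracle)."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(20, 2))
        y = rng.normal(size=20)
        tree2 = fit_tree(X, y, n_splits=2)
        rss2 = np.sum((y - tree2.predict(X)) ** 2)
        for j in range(2):
            for s in np.unique(X[:, j]):
                mask = X[:, j] < s
                if not mask.any() or mask.all():
                    continue
                rss1 = (np.sum((y[mask] - y[mask].mean()) ** 2)
                        + np.sum((y[~mask] - y[~mask].mean()) ** 2))
                assert rss2 <= rss1 + 1e-9


class TestBoosting:
    def test_single_full_strength_tree_interpolates(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([4.0, 1.0, 7.0, 2.0])
        model = mn.BoostedTreeRegressor(n_estimators=1, learning_rate=1.0,
                                        interaction_depth=3).fit(X, y)
        np.testing.assert_allclose(model.predict(X), y, rtol=0, atol=0)

    def test_residual_identity_every_iteration(self, year_frame):
        """r_i = y_i - f(x_i) to 1e-9 relative at every boosting step."""
        frame = year_frame.iloc[:500]
        X, y = frame.drop(columns="no2"), frame["no2"].to_numpy()
        model = mn.BoostedTreeRegressor(n_estimators=25, learning_rate=0.1,
                                        interaction_depth=4).fit(X, y)
        scale = np.abs(y).max()
        # replay the sequential residual update with the stored trees and
        # compare against y - cumulative ensemble prediction at every step
        residuals = y.copy()
        Xv = X.to_numpy(dtype=float)
        for tree, staged in zip(model.trees_, model.staged_predict(X)):
            residuals = residuals - model.learning_rate * tree.predict(Xv)
            assert np.max(np.abs(residuals - (y - staged))) <= 1e-9 * scale
        assert np.max(np.abs(residuals - model.residuals_)) <= 1e-9 * scale

    def test_training_rss_monotone_nonincreasing(self, year_frame):
        frame = year_frame.iloc[:800]
        X, y = frame.drop(columns="no2"), frame["no2"].to_numpy()
        model = mn.BoostedTreeRegressor(n_estimators=50, learning_rate=0.1,
                                        interaction_depth=3).fit(X, y)
        # recompute per-iteration RSS from the stored trees (oracle route)
        rss = np.array([np.sum((y - p) ** 2) for p in model.staged_predict(X)])
        assert np.all(np.diff(rss) <= 1e-9 * rss[0])
        np.testing.assert_allclose(rss, model.train_rss_path_, rtol=1e-9)

    def test_predict_matches_naive_tree_walker(self, small_model, year_frame):
        """Stacked-array traversal equals an independent per-tree walk."""
        rows = year_frame.drop(columns="no2").iloc[:100]
        Xv = rows.to_numpy(dtype=float)

        def walk(tree, x):
            node = 0
            while tree.feature[node] >= 0:
                if x[tree.feature[node]] < tree.threshold[node]:
                    node = tree.left[node]
                else:
                    node = tree.right[node]
            return tree.value[node]

        naive = small_model.learning_rate * np.array(
            [sum(walk(t, x) for t in small_model.trees_) for x in Xv])
        np.testing.assert_allclose(small_model.predict(rows), naive,
                                   rtol=1e-12)

    def test_compiled_and_numpy_traversals_agree(self, small_model,
                                                 year_frame):
        from metnorm import _predict
        X = year_frame.drop(columns="no2").iloc[:200].to_numpy(dtype=float)
        args = (X, small_model._feat, small_model._thr, small_model._left,
                small_model._right, small_model._val,
                small_model.learning_rate)
        np.testing.assert_array_equal(
            _predict.ensemble_predict(*args, use_numba=True),
            _predict.ensemble_predict(*args, use_numba=False))

    def test_empty_model_predicts_zero(self):
        model = mn.BoostedTreeRegressor()
        np.testing.assert_array_equal(model.predict(np.zeros((5, 3))),
                                      np.zeros(5))

    def test_duplicate_rows_get_identical_predictions(self, small_model,
                                                      year_frame):
        row = year_frame.drop(columns="no2").iloc[[10]]
        dup = pd.concat([row] * 4)
        assert np.unique(small_model.predict(dup)).size == 1

    def test_non_finite_response_rejected(self):
        X = np.zeros((12, 2))
        y = np.ones(12)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mn.BoostedTreeRegressor(n_estimators=2).fit(X, y)

    def test_missing_predictor_column_named_in_error(self, small_model,
                                                     year_frame):
        X = year_frame.drop(columns=["no2", "ws"])
        with pytest.raises(KeyError, match="ws"):
            small_model.predict(X)

    def test_predictor_order_permutation_invariance(self, year_frame):
        frame = year_frame.iloc[:400]
        X, y = frame.drop(columns="no2"), frame["no2"]
        m1 = mn.BoostedTreeRegressor(n_estimators=10,
                                     interaction_depth=3).fit(X, y)
        cols = list(X.columns)[::-1]
        m2 = mn.BoostedTreeRegressor(n_estimators=10,
                                     interaction_depth=3).fit(X[cols], y)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X), rtol=1e-9)

    def test_serialisation_round_trip(self, small_model, year_frame):
        X = year_frame.drop(columns="no2").iloc[:50]
        clone = mn.BoostedTreeRegressor.from_json(small_model.to_json())
        np.testing.assert_array_equal(clone.predict(X),
                                      small_model.predict(X))

    def test_sklearn_get_set_params(self):
        model = mn.BoostedTreeRegressor(n_estimators=5)
        params = model.get_params()
        assert params["n_estimators"] == 5
        model.set_params(learning_rate=0.5)
        assert model.learning_rate == 0.5


class TestSplitTrainTest:
    def test_partition_sizes_and_disjointness(self):
        frame = pd.DataFrame({"a": range(10)})
        train, test = mn.split_train_test(frame, 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(range(10))

    def test_floor_arithmetic_on_a_year(self):
        frame = pd.DataFrame({"a": range(8760)})
        train, _ = mn.split_train_test(frame, 0.8, seed=0)
        assert len(train) == 7008

    def test_same_seed_same_partition(self):
        frame = pd.DataFrame({"a": range(50)})
        t1, _ = mn.split_train_test(frame, 0.8, seed=9)
        t2, _ = mn.split_train_test(frame, 0.8, seed=9)
        assert list(t1.index) == list(t2.index)


class TestEvaluate:
    class _Identity:
        def predict(self, X):
            return np.asarray(X, dtype=float).ravel()

    def test_perfect_predictions(self):
        obs = np.array([1.0, 2.0, 3.0])
        m = mn.evaluate(self._Identity(), obs[:, None], obs)
        assert m.pearson_r == 1.0 and m.rmse == 0.0 and m.mean_bias == 0.0

    def test_constant_offset(self):
        obs = np.array([1.0, 2.0, 3.0])
        m = mn.evaluate(self._Identity(), (obs + 2)[:, None], obs)
        assert m.mean_bias == pytest.approx(2.0)
        assert m.rmse == pytest.approx(2.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_zero_variance_marks_r_undefined(self):
        obs = np.array([1.0, 1.0, 1.0])
        m = mn.evaluate(self._Identity(), obs[:, None], obs)
        assert np.isnan(m.pearson_r)
        assert m.rmse == 0.0

    def test_metrics_match_formula_oracle(self):
        rng = np.random.default_rng(5)
        pred = rng.normal(size=200)
        obs = pred + rng.normal(size=200)
        m = mn.evaluate(self._Identity(), pred[:, None], obs)
        assert m.pearson_r == pytest.approx(stats.pearsonr(pred, obs)[0])
        assert m.rmse == pytest.approx(np.sqrt(np.mean((pred - obs) ** 2)))
        assert m.mean_bias == pytest.approx(np.mean(pred - obs))
        assert m.n_test == 200
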