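import numpy as np
import pytest

from hetdti.classifier import (
    ForestConfig,
    ForestModel,
    best_split_exhaustive,
    feature_importance,
    fit_forest,
    gini_impurity,
    gini_index,
    predict_scores,
)
from oracles import cart_best_split_enum


class TestGini:
    @pytest.mark.parametrize("labels,expected", [
        ([1, 1, 1, 1], 0.0),                 # pure node
        ([0, 1], 0.5),                       # balanced binary
        ([1, 1, 1, 0], 0.375),               # 3:1 split
        ([0, 0, 1, 1, 2, 2], 1 - 3 * (1 / 3) ** 2),  # three balanced classes
    ])
    def test_closed_forms(self, labels, expected):
        assert gini_impurity(labels) == pytest.approx(expected)

    def test_invariant_under_label_permutation(self):
        assert gini_impurity([0, 0, 1]) == gini_impurity([1, 1, 0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gini_impurity([])

    def test_index_weighted_hand_case(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 0])
        # split at 1.5: left {0,0} pure, right {1,0} gini 0.5
        assert gini_index(X, y, 0, 1.5) == pytest.approx(0.5 * 0.0 + 0.5 * 0.5)

    def test_perfect_split_is_zero(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([0, 0, 1, 1])
        assert gini_index(X, y, 0, 2.5) == 0.0

    def test_one_sided_split_rejected(self):
        X = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError):
            gini_index(X, [0, 1], 0, 5.0)

    def test_best_split_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.random((6, 3))
            y = rng.integers(0, 2, size=6)
            if len(np.unique(y)) < 2:
                continue
            ours = best_split_exhaustive(X, y)
            oracle = cart_best_split_enum(X, y)
            assert ours[2] == pytest.approx(oracle[2])
            assert (ours[0], ours[1]) == (oracle[0], pytest.approx(oracle[1]))


class TestForest:
    def test_single_tree_fits_separable_data(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [5, 5], [5, 6], [6, 5], [6, 6]],
                     dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cfg = ForestConfig(n_trees=1, max_features="all", bootstrap=False, seed=0)
        model = fit_forest(X, y, cfg)
        np.testing.assert_array_equal(predict_scores(model, X) >= 0.5, y.astype(bool))

    def test_root_split_matches_exhaustive_cart(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            X = rng.random((6, 2))
            y = np.array([0, 0, 0, 1, 1, 1])
            rng.shuffle(y)
            cfg = ForestConfig(n_trees=1, max_features="all", bootstrap=False, seed=0)
            model = fit_forest(X, y, cfg)
            tree = model.trees[0].tree_
            oracle = cart_best_split_enum(X, y)
            achieved = gini_index(X, y, int(tree.feature[0]), float(tree.threshold[0]))
            assert achieved == pytest.approx(oracle[2], abs=1e-12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 5))
        y = (X[:, 0] > 0.5).astype(int)
        cfg = ForestConfig(n_trees=25, seed=7)
        s1 = predict_scores(fit_forest(X, y, cfg), X)
        s2 = predict_scores(fit_forest(X, y, cfg), X)
        np.testing.assert_array_equal(s1, s2)

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 4))
        y = rng.integers(0, 2, size=30)
        model = fit_forest(X, y, ForestConfig(n_trees=10, seed=0))
        s = predict_scores(model, rng.random((10, 4)))
        assert np.all((s >= 0) & (s <= 1))

    def test_single_class_errors(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit_forest(X, [1, 1, 1, 1], ForestConfig(seed=0))

    def test_feature_dimension_mismatch_errors(self):
        rng = np.random.default_rng(4)
        X = rng.random((10, 3))
        y = rng.integers(0, 2, size=10)
        y[0], y[1] = 0, 1
        model = fit_forest(X, y, ForestConfig(n_trees=5, seed=0))
        with pytest.raises(ValueError, match="dimension"):
            predict_scores(model, rng.random((2, 5)))

    def test_oob_accuracy_beats_majority_baseline(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((120, 6))
            y = (X[:, 0] + 0.3 * rng.standard_normal(120) > 0).astype(int)
            model = fit_forest(X, y, ForestConfig(n_trees=200, seed=seed), oob=True)
            baseline = max(y.mean(), 1 - y.mean())
            if model.estimator.oob_score_ > baseline:
                hits += 1
        assert hits >= 9

    def test_more_trees_do_not_hurt_oob(self):
        # monotone-in-expectation: averaged over seeds, 200 trees >= 10 trees
        deltas = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((100, 6))
            y = (X[:, 1] - X[:, 2] + 0.5 * rng.standard_normal(100) > 0).astype(int)
            small = fit_forest(X, y, ForestConfig(n_trees=10, seed=seed), oob=True)
            big = fit_forest(X, y, ForestConfig(n_trees=200, seed=seed), oob=True)
            deltas.append(big.estimator.oob_score_ - small.estimator.oob_score_)
        assert np.mean(deltas) > -0.02


class TestImportance:
    def test_sums_to_one_and_planted_feature_wins(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.random((100, 5))
            y = (X[:, 1] > 0.5).astype(int)  # only feature 1 informative
            model = fit_forest(X, y, ForestConfig(n_trees=50, seed=seed))
            imp = feature_importance(model)
            assert imp.sum() == pytest.approx(1.0)
            assert np.all(imp >= 0)
            if imp.argmax() == 1:
                wins += 1
        assert wins == 10

    def test_unused_feature_importance_zero(self):
        X = np.array([[0.0, 7.0], [1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_forest(X, y, ForestConfig(n_trees=10, bootstrap=False,
                                              max_features="all", seed=0))
        assert feature_importance(model)[1] == 0.0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        X = rng.random((30, 4))
        y = (X[:, 0] > 0.5).astype(int)
        model = fit_forest(X, y, ForestConfig(n_trees=12, seed=3))
        path = tmp_path / "forest.pkl"
        model.save(path)
        loaded = ForestModel.load(path)
        np.testing.assert_array_equal(predict_scores(model, X),
                                      predict_scores(loaded, X))
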