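import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.ensemble import RandomForestClassifier

from circpot import (
    CalibrationTable,
    FractileForestClassifier,
    auc,
    calibrate_fpr,
    cv_auc,
    permutation_importance,
    predict,
    score_to_fractile,
    train_cv_ensemble,
    tune_num_trees,
)

import oracles


def separable_data(seed=0, n=120, p=8):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, p))
    X[:, 0] += 6.0 * y  # classes linearly separable on feature 0
    return X, y


class TestAuc:
    @pytest.mark.parametrize("pos,neg,expected", [
        ([0.9, 0.8], [0.7, 0.1], 1.0),
        ([0.8, 0.2], [0.6, 0.1], 0.75),
        ([0.5, 0.5], [0.5, 0.5], 0.5),  # all ties -> 0.5
    ])
    def test_hand_cases(self, pos, neg, expected):
        assert auc(pos, neg) == expected

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        pos = np.round(rng.random(40), 2)  # rounding forces ties
        neg = np.round(rng.random(50), 2)
        assert abs(auc(pos, neg) - oracles.oracle_auc(pos, neg)) < 1e-12

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestFractile:
    @pytest.mark.parametrize("score,expected", [
        (5.0, 1.0), (2.5, 0.5), (2.0, 0.375), (0.0, 0.0),
    ])
    def test_tie_rule_hand_cases(self, score, expected):
        assert score_to_fractile(score, [1, 2, 3, 4]) == expected

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(2)
        vals = np.round(rng.random(200), 2)
        for s in np.round(rng.random(30), 2):
            assert score_to_fractile(s, vals) == \
                oracles.oracle_fractile(s, vals)

    def test_self_fractiles_uniform(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=1000)
        fracs = np.sort([score_to_fractile(v, vals) for v in vals])
        ecdf = np.arange(1, 1001) / 1000
        assert np.max(np.abs(fracs - ecdf)) <= 0.05

    def test_empty_distribution_errors(self):
        with pytest.raises(ValueError):
            score_to_fractile(0.5, [])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
           st.floats(-1, 2, allow_nan=False))
    def test_fractile_in_unit_interval(self, vals, score):
        assert 0.0 <= score_to_fractile(score, vals) <= 1.0


class TestCvEnsemble:
    def test_separable_data_high_oof_auc(self):
        X, y = separable_data(seed=4)
        model = train_cv_ensemble(X, y, n_trees=50, seed=0)
        assert model.cv_auc_ >= 0.95

    def test_shuffled_labels_near_chance(self):
        X, y = separable_data(seed=5, n=300)
        rng = np.random.default_rng(6)
        model = train_cv_ensemble(X, rng.permutation(y), n_trees=50, seed=0)
        assert 0.4 <= model.cv_auc_ <= 0.6

    def test_folds_disjoint_and_cover(self):
        X, y = separable_data(seed=7)
        model = train_cv_ensemble(X, y, n_trees=10, seed=0)
        assert sorted(np.unique(model.fold_assignment_)) == [0, 1, 2, 3, 4]
        assert model.fold_assignment_.shape == (len(y),)
        assert len(model.models_) == 5
        assert all(np.all(np.diff(vs) >= 0) for vs in model.val_scores_)

    def test_single_class_errors(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        with pytest.raises(ValueError, match="two classes"):
            train_cv_ensemble(X, np.ones(40), n_trees=10, seed=0)

    def test_reproducible_under_seed(self):
        X, y = separable_data(seed=8)
        a = train_cv_ensemble(X, y, n_trees=20, seed=5)
        b = train_cv_ensemble(X, y, n_trees=20, seed=5)
        np.testing.assert_array_equal(a.oof_scores_, b.oof_scores_)
        Xt = np.random.default_rng(9).normal(size=(10, X.shape[1]))
        np.testing.assert_array_equal(a.predict_mean_fractile(Xt),
                                      b.predict_mean_fractile(Xt))

    def test_predict_monotone_in_scores(self):
        X, y = separable_data(seed=10)
        model = train_cv_ensemble(X, y, n_trees=30, seed=1)
        lo = model.predict_mean_fractile(np.full((1, X.shape[1]), -4.0))
        hi = model.predict_mean_fractile(
            np.concatenate([[6.0], np.full(X.shape[1] - 1, 0.0)])[None, :])
        assert hi >= lo

    def test_high_scoring_input_reaches_fractile_one(self):
        X, y = separable_data(seed=11)
        model = train_cv_ensemble(X, y, n_trees=30, seed=1)
        strong = X[y == 1].mean(axis=0) * 4
        mf = model.predict_mean_fractile(strong[None, :])[0]
        assert 0.9 <= mf <= 1.0

    def test_predict_op_with_hand_set_val_scores(self):
        X, y = separable_data(seed=12)
        model = train_cv_ensemble(X, y, n_trees=10, seed=2)
        model.val_scores_ = [np.sort(v) for v in
                             ([1, 2], [1, 3], [2, 4], [0, 1], [1, 1])]
        real_raw = model.raw_scores
        model.raw_scores = lambda X: np.full((X.shape[0], 5), 5.0)
        results = predict(["q"], X[:1], model)
        assert results[0].fractiles.tolist() == [1.0] * 5
        assert results[0].mean_fractile == 1.0
        model.raw_scores = real_raw


class TestTuning:
    def test_returned_value_maximizes_cv_auc(self):
        X, y = separable_data(seed=13, n=100)
        grid = [5, 20, 60]
        best = tune_num_trees(X, y, grid=grid, seed=3)
        best_auc = cv_auc(X, y, n_trees=best, seed=3)
        for t in grid:
            assert best_auc >= cv_auc(X, y, n_trees=t, seed=3)

    def test_tie_prefers_smallest(self):
        # grid of one value trivially returns it
        X, y = separable_data(seed=14, n=60)
        assert tune_num_trees(X, y, grid=[30], seed=0) == 30

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            tune_num_trees(*separable_data(seed=0), grid=[], seed=0)


class TestCalibration:
    def test_direct_count(self):
        table = calibrate_fpr([0.1, 0.4, 0.6, 0.9],
                              cutoffs=np.array([0.0, 0.5, 1.0]))
        assert table.lookup(0.5) == 0.5
        assert table.lookup(0.0) == 1.0
        assert table.lookup(1.0) == 0.0

    def test_cutoff_above_max_negative_is_zero(self):
        # default dense grid: queries above every negative fractile -> 0
        table = calibrate_fpr([0.1, 0.4, 0.6, 0.9])
        assert table.lookup(0.91) == 0.0
        assert table.lookup(1.0) == 0.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(15)
        table = calibrate_fpr(rng.random(500))
        assert np.all(np.diff(table.fpr) <= 1e-12)
        assert table.fpr[0] == 1.0

    def test_tabulated_cutoffs_reproduce_tail_fractions(self):
        rng = np.random.default_rng(16)
        fracs = rng.random(400)
        table = calibrate_fpr(fracs)
        for t in (0.0, 0.25, 0.5, 0.75, 0.95):
            assert table.lookup(t) == np.mean(fracs >= t)

    def test_empty_negatives_error(self):
        with pytest.raises(ValueError):
            calibrate_fpr([])

    def test_json_roundtrip(self):
        table = calibrate_fpr([0.2, 0.8], cutoffs=np.array([0.0, 0.5, 1.0]))
        back = CalibrationTable.from_json(table.to_json())
        np.testing.assert_array_equal(back.cutoffs, table.cutoffs)
        np.testing.assert_array_equal(back.fpr, table.fpr)


class TestPermutationImportance:
    def test_score_vector_length_and_constant_feature(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(150, 6))
        X[:, 3] = 1.0  # constant
        y = (X[:, 0] > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=40,
                                        random_state=0).fit(X, y)
        imp = permutation_importance(forest, X, y, seed=0)
        assert imp.shape == (6,)
        assert imp[3] == 0.0

    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(18)
        n = 200
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 20))
        X[:, 7] = y + rng.normal(scale=0.3, size=n)
        forest = RandomForestClassifier(n_estimators=60,
                                        random_state=1).fit(X, y)
        imp = permutation_importance(forest, X, y, seed=1)
        assert int(np.argmax(imp)) == 7
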