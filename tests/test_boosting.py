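import json

import numpy as np
import pytest

from shapims import boosting
from shapims.boosting import (ClassificationMetrics, LabeledSubset,
                              RegressionTree, TrainingConfig, TreeEnsemble,
                              downsample_negatives, evaluate,
                              import_ensemble, make_labels, predict_class,
                              predict_probability, predict_raw,
                              prediction_image, split_holdout,
                              train_ensemble)
from shapims.ims_data import AnnotationMask, IMSDataset


def stump(feature=0, threshold=2.5, left=-1.0, right=1.0,
          cover=(10.0, 4.0, 6.0)):
    return RegressionTree(
        children_left=[1, -1, -1], children_right=[2, -1, -1],
        feature=[feature, -1, -1], threshold=[threshold, np.nan, np.nan],
        value=[0.0, left, right], cover=list(cover),
    )


def separable_dataset(n=32, seed=0):
    """POS iff feature 0 > 5; other features are noise."""
    rng = np.random.default_rng(seed)
    x0 = np.concatenate([rng.uniform(6, 10, n // 2),
                         rng.uniform(0, 4, n // 2)])
    X = np.column_stack([x0, rng.uniform(0, 1, n), rng.uniform(0, 1, n)])
    coords = np.column_stack([np.arange(n), np.zeros(n, int)])
    ds = IMSDataset(X, coords, [100.0, 200.0, 300.0])
    ls = LabeledSubset(np.arange(n),
                       np.concatenate([np.ones(n // 2, int),
                                       -np.ones(n // 2, int)]))
    return ds, ls


class TestLabeling:
    def test_make_labels_mapping(self):
        mask = AnnotationMask("c", [1, 0, -1, 0])
        ls = make_labels(mask)
        np.testing.assert_array_equal(ls.pixel_indices, [0, 1, 3])
        np.testing.assert_array_equal(ls.labels, [1, -1, -1])

    def test_make_labels_counts(self):
        mask = AnnotationMask("c", [1] * 3 + [0] * 5 + [-1] * 2)
        assert len(make_labels(mask)) == 8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_labels(AnnotationMask("c", [1, 1, -1]))


class TestDownsampling:
    def test_exact_quarter(self):
        ls = LabeledSubset(np.arange(100),
                           np.r_[np.ones(10, int), -np.ones(90, int)])
        out = downsample_negatives(ls, 0.25, seed=0)
        assert out.n_pos == 10 and out.n_neg == 30

    def test_shortfall_keeps_all_and_warns(self):
        ls = LabeledSubset(np.arange(30),
                           np.r_[np.ones(10, int), -np.ones(20, int)])
        with pytest.warns(UserWarning, match="keeping all negatives"):
            out = downsample_negatives(ls, 0.25, seed=0)
        assert out.n_neg == 20

    def test_deterministic(self):
        ls = LabeledSubset(np.arange(100),
                           np.r_[np.ones(10, int), -np.ones(90, int)])
        a = downsample_negatives(ls, 0.25, seed=5)
        b = downsample_negatives(ls, 0.25, seed=5)
        np.testing.assert_array_equal(a.pixel_indices, b.pixel_indices)

    def test_bad_fraction(self):
        ls = LabeledSubset([0, 1], [1, -1])
        with pytest.raises(ValueError):
            downsample_negatives(ls, 1.0, seed=0)


class TestHoldout:
    def test_stratified_counts(self):
        ls = LabeledSubset(np.arange(16),
                           np.r_[np.ones(8, int), -np.ones(8, int)])
        train, test = split_holdout(ls, 0.25, seed=0)
        assert test.n_pos == 2 and test.n_neg == 2
        assert train.n_pos == 6 and train.n_neg == 6

    def test_partition(self):
        ls = LabeledSubset(np.arange(20),
                           np.r_[np.ones(8, int), -np.ones(12, int)])
        train, test = split_holdout(ls, 0.3, seed=1)
        got = np.sort(np.r_[train.pixel_indices, test.pixel_indices])
        np.testing.assert_array_equal(got, ls.pixel_indices)
        assert not set(train.pixel_indices) & set(test.pixel_indices)

    def test_deterministic(self):
        ls = LabeledSubset(np.arange(20),
                           np.r_[np.ones(8, int), -np.ones(12, int)])
        a = split_holdout(ls, 0.3, seed=9)[1]
        b = split_holdout(ls, 0.3, seed=9)[1]
        np.testing.assert_array_equal(a.pixel_indices, b.pixel_indices)

    def test_tiny_class_rejected(self):
        ls = LabeledSubset([0, 1, 2], [1, -1, -1])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_holdout(ls, 0.5, seed=0)


class TestTraining:
    def test_zero_trees_gives_base_rate_log_odds(self):
        ds, ls = separable_dataset()
        ens = train_ensemble(ds, ls, TrainingConfig(n_trees=0))
        expected = np.log(ls.n_pos / ls.n_neg)
        raw = ens.predict_raw(ds.intensities)
        np.testing.assert_allclose(raw, expected)

    def test_separable_feature_reaches_perfect_training_accuracy(self):
        ds, ls = separable_dataset()
        cfg = TrainingConfig(n_trees=10, max_depth=1, row_subsample=1.0,
                             col_subsample=1.0, min_child_cover=1)
        ens = train_ensemble(ds, ls, cfg)
        pred = predict_class(ens, ds.intensities[ls.pixel_indices])
        assert evaluate(pred, ls.labels).balanced_accuracy == 1.0

    def test_cover_conservation_and_positivity(self):
        ds, ls = separable_dataset(seed=3)
        ens = train_ensemble(ds, ls, TrainingConfig(n_trees=20, seed=3))
        for tree in ens.trees:
            assert tree.check_cover_conservation()
            assert (tree.cover > 0).all()
        # root cover equals the full training-set size
        assert all(t.cover[0] == len(ls) for t in ens.trees)

    def test_training_loss_non_increasing_without_subsampling(self):
        ds, ls = separable_dataset(seed=4)
        cfg = TrainingConfig(n_trees=30, row_subsample=1.0,
                             col_subsample=1.0, seed=4)
        ens = train_ensemble(ds, ls, cfg)
        X = ds.intensities[ls.pixel_indices]
        t = (ls.labels + 1) / 2
        raw = np.full(len(ls), ens.base_prediction)
        losses = []
        for tree in [None] + ens.trees:
            if tree is not None:
                raw = raw + ens.learning_rate * tree.predict(X)
            p = 1 / (1 + np.exp(-raw))
            losses.append(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_deterministic_under_seed(self):
        ds, ls = separable_dataset(seed=5)
        a = train_ensemble(ds, ls, TrainingConfig(n_trees=15, seed=7))
        b = train_ensemble(ds, ls, TrainingConfig(n_trees=15, seed=7))
        np.testing.assert_array_equal(a.predict_raw(ds.intensities),
                                      b.predict_raw(ds.intensities))

    def test_empty_training_set_rejected(self):
        ds, _ = separable_dataset()
        with pytest.raises(ValueError):
            train_ensemble(ds, LabeledSubset([], []), TrainingConfig())


class TestPrediction:
    def test_empty_ensemble_returns_base(self):
        ens = TreeEnsemble(0.7, 0.3, [], 3)
        assert predict_raw(ens, [1.0, 2.0, 3.0]) == 0.7

    def test_two_stumps_with_shrinkage(self):
        ens = TreeEnsemble(0.0, 0.5, [stump(), stump()], 1)
        assert predict_raw(ens, [3.0]) == pytest.approx(1.0)

    def test_equality_routes_left(self):
        ens = TreeEnsemble(0.0, 1.0, [stump(threshold=2.5)], 1)
        assert predict_raw(ens, [2.5]) == -1.0

    @pytest.mark.parametrize("raw, p", [
        (0.0, 0.5), (np.log(3), 0.75), (-np.log(3), 0.25),
    ])
    def test_probability_closed_forms(self, raw, p):
        ens = TreeEnsemble(raw, 0.3, [], 1)
        assert predict_probability(ens, [0.0]) == pytest.approx(p)

    @pytest.mark.parametrize("p_raw, eta, expected", [
        (0.0, 0.5, 1),        # p = 0.5 ties to +1
        (-0.05, 0.5, -1),
        (np.log(9), 0.95, -1),  # p = 0.9 < 0.95
    ])
    def test_class_threshold(self, p_raw, eta, expected):
        ens = TreeEnsemble(p_raw, 0.3, [], 1)
        assert predict_class(ens, [0.0], eta) == expected

    def test_class_monotone_in_eta(self):
        rng = np.random.default_rng(0)
        ens = TreeEnsemble(0.0, 1.0, [stump()], 1)
        X = rng.uniform(0, 5, size=(50, 1))
        prev = predict_class(ens, X, 0.1)
        for eta in (0.3, 0.5, 0.7, 0.9):
            cur = predict_class(ens, X, eta)
            assert not ((prev == -1) & (cur == 1)).any()
            prev = cur

    def test_wrong_length_rejected(self):
        ens = TreeEnsemble(0.0, 0.3, [], 3)
        with pytest.raises(ValueError):
            predict_raw(ens, [1.0])


class TestMetrics:
    def test_definitions(self):
        m = ClassificationMetrics(tp=2, fp=1, tn=3, fn=0)
        assert m.recall == 1.0
        assert m.specificity == 0.75
        assert m.balanced_accuracy == 0.875
        assert m.precision == pytest.approx(2 / 3)

    def test_undefined_rates(self):
        m = evaluate([-1, -1], [-1, -1])
        assert m.recall is None
        assert m.balanced_accuracy is None
        assert m.specificity == 1.0

    def test_perfect(self):
        m = evaluate([1, -1, 1], [1, -1, 1])
        assert (m.precision, m.recall, m.specificity,
                m.balanced_accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [1, -1])
        with pytest.raises(ValueError):
            evaluate([1], [1, -1])


class TestPredictionImage:
    def test_constant_positive_ensemble(self, tiny_ds):
        ens = TreeEnsemble(2.0, 0.3, [], 3)
        img = prediction_image(ens, tiny_ds)
        np.testing.assert_array_equal(img.values, np.ones((2, 2)))

    def test_dimensions_match_ion_image(self, demo_phantom):
        ds, _, _ = demo_phantom
        ens = TreeEnsemble(0.0, 0.3, [], ds.n_features)
        assert prediction_image(ens, ds).shape == ds.ion_image(0).shape

    def test_phantom_prediction_matches_region(self, demo_phantom,
                                               demo_results):
        ds, masks, gt = demo_phantom
        img = demo_results.prediction_image()
        rows, cols = gt.pixel_coords.T
        predicted_pos = img.values[rows, cols] > 0
        truth = gt.region_of_pixel == "target"
        jacc = ((predicted_pos & truth).sum()
                / (predicted_pos | truth).sum())
        assert jacc >= 0.95


class TestSerialization:
    def test_json_round_trip(self):
        ds, ls = separable_dataset(seed=6)
        ens = train_ensemble(ds, ls, TrainingConfig(n_trees=5, seed=6))
        back = import_ensemble(ens.to_json())
        np.testing.assert_allclose(back.predict_raw(ds.intensities),
                                   ens.predict_raw(ds.intensities),
                                   atol=1e-12)

    def test_single_stump_dump(self):
        dump = json.dumps({
            "base_prediction": 0.0, "learning_rate": 1.0, "n_features": 1,
            "trees": [{"nodes": [
                {"id": 0, "is_leaf": False, "feature": 0, "threshold": 2.5,
                 "left": 1, "right": 2, "value": 0.0, "cover": 10.0},
                {"id": 1, "is_leaf": True, "feature": -1, "threshold": None,
                 "left": -1, "right": -1, "value": -1.0, "cover": 4.0},
                {"id": 2, "is_leaf": True, "feature": -1, "threshold": None,
                 "left": -1, "right": -1, "value": 1.0, "cover": 6.0},
            ]}],
        })
        ens = import_ensemble(dump)
        assert predict_raw(ens, [3.0]) == 1.0

    def test_missing_cover_rejected(self):
        dump = json.dumps({
            "base_prediction": 0.0, "learning_rate": 1.0, "n_features": 1,
            "trees": [{"nodes": [
                {"id": 0, "is_leaf": True, "feature": -1, "threshold": None,
                 "left": -1, "right": -1, "value": 1.0},
            ]}],
        })
        with pytest.raises(ValueError, match="cover required"):
            import_ensemble(dump)


class TestXGBoostImport:
    def test_margins_match_external_booster(self, demo_phantom):
        xgb = pytest.importorskip("xgboost")
        ds, masks, _ = demo_phantom
        ls = make_labels(masks["target"])
        X = ds.intensities[ls.pixel_indices]
        y = (ls.labels + 1) // 2
        bst = xgb.train(
            {"objective": "binary:logistic", "max_depth": 4, "eta": 0.3,
             "base_score": 0.5, "lambda": 1.0, "tree_method": "exact"},
            xgb.DMatrix(X, label=y), num_boost_round=20,
        )
        ens = boosting.from_xgboost(bst)
        ours = ens.predict_raw(X[:100])
        theirs = bst.predict(xgb.DMatrix(X[:100]), output_margin=True)
        # the external booster reports float32 margins, so agreement is
        # bounded by float32 resolution at the margin's magnitude
        assert np.allclose(ours, theirs, rtol=1e-6, atol=1e-6)
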