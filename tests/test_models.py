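"""Kennard-Stone splitting, the three discriminant models, and evaluation."""

import itertools

import numpy as np
import pytest

from berrytrace import (
    ELMClassifier,
    RBFNetClassifier,
    SpectralDataset,
    WavelengthAxis,
    default_origin_models,
    evaluate,
    kennard_stone_split,
    make_sample_library,
    search_elm,
    train_elm,
    train_rbf_net,
    train_svm,
)
from berrytrace.models import (
    DEFAULT_SVM_GRID,
    kennard_stone_indices,
    macro_mean_accuracy,
)


def make_ds(X, y=None, ids=None):
    X = np.asarray(X, float)
    return SpectralDataset(X, WavelengthAxis(np.arange(X.shape[1], dtype=float)),
                           y=y, ids=ids)


def separated_library(seed, n_per_class=40, axis=None):
    """Well-separated classes: between-class offsets far exceed the noise."""
    if axis is None:
        axis = WavelengthAxis(np.linspace(950.0, 1650.0, 40))
    models = default_origin_models(offset_scale=6.0, noise_sd=0.01)
    return make_sample_library(models, n_per_class, axis, seed=seed)


class TestKennardStone:
    def test_stratified_2to1_takes_200_of_each_300(self, instrument_axis):
        models = default_origin_models()
        ds = make_sample_library(models, 300, instrument_axis, seed=0)
        split = kennard_stone_split(ds, ratio=2.0, per_class=True)
        assert len(split.calibration_ids) == 800
        assert len(split.prediction_ids) == 400
        for cls in (1, 2, 3, 4):
            cls_ids = set(map(int, ds.ids[ds.y == cls]))
            assert len(cls_ids & set(map(int, split.calibration_ids))) == 200

    def test_two_points_quota_two_selects_both(self):
        idx = kennard_stone_indices(np.array([[0.0], [5.0]]), 2)
        assert set(idx) == {0, 1}

    def test_matches_exhaustive_greedy_oracle(self):
        """8 random 2-D points, quota 4, vs a brute-force max-min oracle."""
        rng = np.random.default_rng(13)
        X = rng.uniform(size=(8, 2))
        selected = kennard_stone_indices(X, 4)

        # oracle: exhaustive greedy — start from the farthest pair, then at
        # each step pick the point maximizing the min distance to the set
        def dist(i, j):
            return np.linalg.norm(X[i] - X[j])

        pair = max(itertools.combinations(range(8), 2), key=lambda p: dist(*p))
        chosen = list(pair)
        while len(chosen) < 4:
            rest = [i for i in range(8) if i not in chosen]
            chosen.append(max(rest,
                              key=lambda i: min(dist(i, j) for j in chosen)))
        assert set(selected) == set(chosen)
        np.testing.assert_array_equal(selected[:2], sorted(pair))

    def test_deterministic_under_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(30, 5))
        ds = make_ds(X, y=np.ones(30, dtype=int), ids=np.arange(30))
        perm = rng.permutation(30)
        ds_perm = make_ds(X[perm], y=np.ones(30, dtype=int), ids=perm)
        a = kennard_stone_split(ds, ratio=2.0)
        b = kennard_stone_split(ds_perm, ratio=2.0)
        np.testing.assert_array_equal(a.calibration_ids, b.calibration_ids)

    def test_quota_below_two_is_error(self):
        ds = make_ds(np.random.default_rng(0).uniform(size=(4, 3)),
                     y=np.array([1, 1, 1, 1]))
        with pytest.raises(ValueError):
            kennard_stone_split(ds, ratio=0.1)


class TestELM:
    def test_exact_interpolation_with_square_hidden_matrix(self):
        """h = n distinct samples: the network interpolates the training set."""
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(12, 5))
        y = rng.integers(1, 5, size=12)
        model = ELMClassifier(n_hidden=12, random_state=1).fit(X, y)
        assert np.all(model.predict(X) == y)

    def test_fixed_seed_reproducible(self, small_library):
        ds = small_library
        a = train_elm(ds, h=20, seed=5)
        b = train_elm(ds, h=20, seed=5)
        np.testing.assert_array_equal(a.input_weights_, b.input_weights_)
        np.testing.assert_array_equal(a.predict(ds.X), b.predict(ds.X))

    def test_recovers_separated_classes_across_seeds(self):
        """>= 95% mean prediction accuracy over 20 seeds, variance < 2 points."""
        accs = []
        for seed in range(20):
            ds = separated_library(seed)
            split = kennard_stone_split(ds)
            cal = np.isin(ds.ids, split.calibration_ids)
            model = train_elm(ds.subset(np.nonzero(cal)[0]), h=30, seed=seed)
            rep = evaluate(model, ds.subset(np.nonzero(~cal)[0]))
            accs.append(rep.mean_accuracy)
        assert np.mean(accs) >= 95.0
        assert np.std(accs) < 2.0

    def test_search_single_value_range(self, small_library):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            h, model = search_elm(small_library, h_range=range(7, 8))
        assert h == 7 and model.n_hidden == 7

    def test_search_matches_full_scan_oracle(self):
        ds = separated_library(2, n_per_class=10)
        h_range = range(1, 21)
        h, _ = search_elm(ds, h_range=h_range, seed=4)
        errs = []
        for hh in h_range:
            m = train_elm(ds, hh, seed=4)
            errs.append(float(np.mean(m.predict(ds.X) != ds.y)))
        best = min(errs)
        assert errs[h - 1] == best
        assert h == 1 + errs.index(best)      # smallest h on ties

    def test_ceiling_warning(self):
        rng = np.random.default_rng(0)
        # pure noise labels: training error never reaches zero
        ds = make_ds(rng.uniform(size=(40, 6)), y=rng.integers(1, 5, 40))
        # noise labels cannot be fit by the ceiling h, so the warning fires
        with pytest.warns(UserWarning, match="ceiling"):
            search_elm(ds, h_range=range(5, 6))


class TestRBFNet:
    def test_tiny_spread_interpolates_distinct_points(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(15, 4))
        y = rng.integers(1, 5, size=15)
        model = RBFNetClassifier(spread=1e-3).fit(X, y)
        assert np.all(model.predict(X) == y)

    def test_response_is_half_at_radius_equal_to_spread(self):
        model = RBFNetClassifier(spread=2.0, standardize=False)
        model.centers_ = np.array([[0.0]])
        g = model._design(np.array([[2.0]]))
        assert g[0, 0] == pytest.approx(0.5, abs=1e-3)   # 0.8326 ~ sqrt(ln 2)

    def test_single_class_is_always_perfect(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(10, 3))
        y = np.full(10, 2)
        for spread in (0.1, 1.0, 50.0):
            model = RBFNetClassifier(spread=spread).fit(X, y)
            assert np.all(model.predict(X) == 2)

    def test_grid_choice_close_to_exhaustive_oracle(self):
        """CV-selected spread within 2 accuracy points of the grid optimum."""
        ds = separated_library(8, n_per_class=20)
        grid = (0.1, 0.5, 1.0, 3.0, 10.0, 50.0)
        split = kennard_stone_split(ds)
        cal_rows = np.nonzero(np.isin(ds.ids, split.calibration_ids))[0]
        pred_rows = np.nonzero(np.isin(ds.ids, split.prediction_ids))[0]
        ds_cal, ds_pred = ds.subset(cal_rows), ds.subset(pred_rows)
        spread, model = train_rbf_net(ds_cal, spread_grid=grid, cv=3, seed=0)
        chosen_acc = evaluate(model, ds_pred).mean_accuracy
        oracle_best = max(
            evaluate(RBFNetClassifier(spread=s).fit(ds_cal.X, ds_cal.y),
                     ds_pred).mean_accuracy for s in grid)
        assert chosen_acc >= oracle_best - 2.0

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ValueError):
            RBFNetClassifier(spread=0.0).fit(np.eye(3), np.array([1, 2, 3]))


class TestSVM:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, size=(20, 2)),
                       rng.normal(3, 0.1, size=(20, 2))])
        y = np.repeat([1, 2], 20)
        ds = make_ds(X, y=y)
        _, model = train_svm(ds, cv=4)
        assert np.all(model.predict(X) == y)

    def test_single_point_grid_returned(self, small_library):
        grid = {"svc__C": [4.0], "svc__gamma": [0.25]}
        best, _ = train_svm(small_library, grid=grid, cv=3)
        assert best == {"c": 4.0, "g": 0.25}

    def test_default_grid_spans_reported_optima(self):
        # (c, g) = (256, 0.0118) must lie inside the default search box
        cs, gs = DEFAULT_SVM_GRID["svc__C"], DEFAULT_SVM_GRID["svc__gamma"]
        assert min(cs) <= 256 <= max(cs)
        assert min(gs) <= 0.0118 <= max(gs)

    def test_rbf_kernel_solves_xor_where_linear_cannot(self):
        """Brute-force linear control fails XOR; the RBF grid model does not."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(4)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        labels = np.array([1, 1, 2, 2])
        X = np.vstack([c + rng.normal(0, 0.08, size=(15, 2)) for c in centers])
        y = np.repeat(labels, 15)
        ds = make_ds(X, y=y)
        grid = {"svc__C": [1.0, 16.0, 256.0], "svc__gamma": [0.1, 1.0, 10.0]}
        _, rbf_model = train_svm(ds, grid=grid, cv=3)
        rbf_acc = np.mean(rbf_model.predict(X) == y)
        linear_acc = max(
            np.mean(SVC(kernel="linear", C=c).fit(X, y).predict(X) == y)
            for c in (0.1, 1.0, 10.0, 100.0))
        assert rbf_acc > 0.9
        assert linear_acc < 0.9

    def test_nonpositive_parameters_rejected(self, small_library):
        with pytest.raises(ValueError):
            train_svm(small_library, grid={"svc__C": [-1.0],
                                           "svc__gamma": [0.1]})


class _FixedPredictor:
    """Stub classifier returning stored predictions, for evaluation tests."""

    def __init__(self, classes, predictions):
        self.classes_ = np.asarray(classes)
        self._pred = np.asarray(predictions)

    def predict(self, X):
        return self._pred


def predictions_with_accuracy(per_class_pct, n_per_class=100):
    """Build (y_true, y_pred) realizing given per-class accuracies."""
    y_true, y_pred = [], []
    for cls, pct in zip((1, 2, 3, 4), per_class_pct):
        n_correct = int(round(n_per_class * pct / 100))
        wrong_cls = cls % 4 + 1
        y_true += [cls] * n_per_class
        y_pred += [cls] * n_correct + [wrong_cls] * (n_per_class - n_correct)
    return np.array(y_true), np.array(y_pred)


class TestEvaluate:
    @pytest.mark.parametrize("cells,expected_mean", [
        ((96.0, 88.0, 86.0, 94.0), 91.00),
        ((97.0, 86.0, 83.0, 99.0), 91.25),
        ((100.0, 92.5, 96.0, 99.5), 97.00),
        ((98.0, 87.0, 79.0, 97.0), 90.25),
        ((99.0, 83.0, 76.0, 95.0), 88.25),
        ((100.0, 92.5, 93.5, 99.0), 96.25),
    ])
    def test_macro_mean_matches_published_row_arithmetic(self, cells, expected_mean):
        """Every per-class accuracy row averages to its published mean cell."""
        y_true, y_pred = predictions_with_accuracy(cells, n_per_class=200)
        model = _FixedPredictor([1, 2, 3, 4], y_pred)
        ds = make_ds(np.zeros((len(y_true), 3)), y=y_true)
        rep = evaluate(model, ds, "calibration")
        np.testing.assert_allclose(rep.per_class_accuracy, cells)
        assert rep.mean_accuracy == pytest.approx(expected_mean)
        assert macro_mean_accuracy(np.array(cells)) == pytest.approx(expected_mean)

    def test_perfect_predictions(self):
        y = np.repeat([1, 2, 3, 4], 5)
        rep = evaluate(_FixedPredictor([1, 2, 3, 4], y),
                       make_ds(np.zeros((20, 2)), y=y))
        assert rep.mean_accuracy == 100.0
        np.testing.assert_array_equal(rep.confusion, 5 * np.eye(4))

    def test_confusion_rows_sum_to_class_counts(self):
        y_true, y_pred = predictions_with_accuracy((80.0, 60.0, 100.0, 90.0), 10)
        rep = evaluate(_FixedPredictor([1, 2, 3, 4], y_pred),
                       make_ds(np.zeros((40, 2)), y=y_true))
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [10] * 4)

    def test_unseen_label_is_error(self):
        ds = make_ds(np.zeros((4, 2)), y=np.array([1, 2, 3, 5]))
        with pytest.raises(ValueError, match="not seen"):
            evaluate(_FixedPredictor([1, 2, 3, 4], np.ones(4, dtype=int)), ds)


class TestSeparationSanity:
    """Two-sided check: strong separation is learnable, none is chance."""

    @pytest.mark.parametrize("model_name", ["svm", "nn-rbf", "elm"])
    def test_high_accuracy_under_strong_separation(self, model_name):
        ds = separated_library(21, n_per_class=30)
        split = kennard_stone_split(ds)
        cal = np.nonzero(np.isin(ds.ids, split.calibration_ids))[0]
        pred = np.nonzero(np.isin(ds.ids, split.prediction_ids))[0]
        model = _fit_named(model_name, ds.subset(cal), seed=21)
        assert evaluate(model, ds.subset(pred)).mean_accuracy >= 95.0

    @pytest.mark.parametrize("model_name", ["svm", "nn-rbf", "elm"])
    def test_chance_level_without_separation(self, model_name):
        accs = []
        for seed in range(6):
            axis = WavelengthAxis(np.linspace(950.0, 1650.0, 40))
            models = default_origin_models(offset_scale=0.0, noise_sd=0.01)
            ds = make_sample_library(models, 60, axis, seed=100 + seed)
            split = kennard_stone_split(ds)
            cal = np.nonzero(np.isin(ds.ids, split.calibration_ids))[0]
            pred = np.nonzero(np.isin(ds.ids, split.prediction_ids))[0]
            model = _fit_named(model_name, ds.subset(cal), seed=seed)
            accs.append(evaluate(model, ds.subset(pred)).mean_accuracy)
        assert 20.0 <= np.mean(accs) <= 30.0


def _fit_named(name, ds_cal, seed):
    if name == "svm":
        grid = {"svc__C": [1.0, 32.0], "svc__gamma": [0.01, 0.1]}
        return train_svm(ds_cal, grid=grid, cv=3, seed=seed)[1]
    if name == "nn-rbf":
        return train_rbf_net(ds_cal, spread_grid=(0.5, 1.0, 3.0, 10.0),
                             cv=3, seed=seed)[1]
    return train_elm(ds_cal, h=30, seed=seed)
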