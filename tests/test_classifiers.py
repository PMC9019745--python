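import numpy as np
import pytest

from temposeg.classifiers import (
    LabeledDataset,
    LinearClassifier,
    predict_mask,
    split_train_validation,
    train,
    validation_accuracy,
)
from temposeg.errors import DimensionError, ValidationError
from temposeg.movie_io import FeatureMatrix


def make_ds(x, y, seed=0):
    return LabeledDataset(features=np.asarray(x, float), labels=y, split_seed=seed)


def separable_toy(copies=50):
    x = np.array([[0.1], [0.9]] * copies)
    y = np.array([0, 1] * copies)
    return make_ds(x, y)


class TestSplit:
    def test_headline_scale_counts(self, rng):
        x = rng.random((6400, 4))
        y = np.concatenate([np.ones(5500, int), np.zeros(900, int)])
        tr, va = split_train_validation(make_ds(x, y), ratio=(8, 1))
        assert va.class_counts() == {1: round(5500 / 9), 0: round(900 / 9)}
        assert tr.class_counts() == {1: 5500 - 611, 0: 900 - 100}
        assert tr.m + va.m == 6400

    def test_nine_points_split_eight_one(self, rng):
        x = rng.random((18, 3))
        y = np.repeat([0, 1], 9)
        tr, va = split_train_validation(make_ds(x, y), ratio=(8, 1))
        assert va.class_counts() == {0: 1, 1: 1}
        assert tr.class_counts() == {0: 8, 1: 8}

    def test_split_is_deterministic_and_disjoint(self, rng):
        x = rng.random((100, 2))
        y = (rng.random(100) > 0.3).astype(int)
        ds = make_ds(x, y, seed=5)
        tr1, va1 = split_train_validation(ds)
        tr2, va2 = split_train_validation(ds)
        np.testing.assert_array_equal(tr1.features, tr2.features)
        np.testing.assert_array_equal(va1.features, va2.features)
        combined = np.vstack([tr1.features, va1.features])
        assert combined.shape[0] == 100
        # every original row appears exactly once
        order = np.lexsort(combined.T)
        orig = np.lexsort(x.T)
        np.testing.assert_allclose(combined[order], x[orig])

    def test_tiny_class_rejected(self, rng):
        x = rng.random((10, 2))
        y = np.array([1] * 9 + [0])
        with pytest.raises(ValidationError):
            split_train_validation(make_ds(x, y))


class TestTrain:
    @pytest.mark.parametrize("kind", ["logreg", "svm"])
    def test_separable_toy_perfect(self, kind):
        ds = separable_toy()
        model = train(ds, kind=kind)
        assert validation_accuracy(model, ds) == 1.0

    @pytest.mark.parametrize("kind", ["logreg", "svm"])
    def test_xor_is_not_linearly_separable(self, kind):
        # best linear separator on 4 XOR points classifies at most 3 of 4
        x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        ds = make_ds(np.tile(x, (10, 1)), np.tile(y, 10))
        model = train(ds, kind=kind)
        assert validation_accuracy(model, ds) <= 0.75

    def test_single_class_rejected(self):
        ds = make_ds(np.random.default_rng(0).random((10, 2)), np.ones(10, int))
        with pytest.raises(ValidationError):
            train(ds, kind="svm")

    def test_logreg_probability_bounds_and_threshold(self):
        ds = separable_toy()
        model = train(ds, kind="logreg")
        p = model.predict_proba(ds.features)
        assert ((p > 0) & (p < 1)).all()
        # prediction is exactly the p >= 0.5 rule
        np.testing.assert_array_equal(model.predict(ds.features), (p >= 0.5))
        # sigmoid(0) = 0.5 exactly
        zero_model = LinearClassifier(
            weights=np.zeros(1), bias=0.0, kind="logreg", trained_on_n=1
        )
        assert zero_model.predict_proba(np.array([[3.0]]))[0] == 0.5

    def test_logreg_permutation_invariance(self, rng):
        x = rng.random((200, 5))
        y = (x[:, 0] + 0.1 * rng.standard_normal(200) > 0.5).astype(int)
        ds = make_ds(x, y)
        perm = rng.permutation(200)
        ds_p = make_ds(x[perm], y[perm])
        val = make_ds(rng.random((100, 5)), (rng.random(100) > 0.5).astype(int))
        a = validation_accuracy(train(ds, "logreg"), val)
        b = validation_accuracy(train(ds_p, "logreg"), val)
        assert abs(a - b) < 1e-6

    def test_svm_ignores_non_support_vectors(self, rng):
        x = np.vstack([rng.normal(size=(60, 2)) * 0.2,
                       rng.normal(size=(60, 2)) * 0.2 + 2.0])
        y = np.repeat([0, 1], 60)
        ds = make_ds(x, y)
        hp = {"tol": 1e-10, "max_iter": 200000}
        model = train(ds, "svm", hyperparams=hp)
        margin = np.abs(model.decision_function(x))
        keep = margin <= 1.5  # support vectors + near-margin points
        assert keep.sum() < 120 and keep.sum() >= 2
        model2 = train(make_ds(x[keep], y[keep]), "svm", hyperparams=hp)
        cos = np.dot(model.weights, model2.weights) / (
            np.linalg.norm(model.weights) * np.linalg.norm(model2.weights)
        )
        assert cos > 0.999
        assert abs(model.bias - model2.bias) < 0.05 * max(1, abs(model.bias))


class TestPredictMask:
    def _features(self, values, h, w, start=1):
        return FeatureMatrix(
            values=values, n_frames=values.shape[1], start_frame=start, shape_hw=(h, w)
        )

    def test_reshape_to_frame(self, rng):
        model = LinearClassifier(
            weights=np.array([1.0]), bias=-0.5, kind="svm", trained_on_n=1
        )
        vals = rng.random((12, 1))
        mask = predict_mask(model, self._features(vals, 3, 4, start=9))
        assert mask.values.shape == (3, 4)
        assert mask.frame_index == 9
        np.testing.assert_array_equal(
            mask.values.ravel(), (vals[:, 0] >= 0.5).astype(np.uint8)
        )

    def test_constant_features_constant_mask(self):
        model = LinearClassifier(
            weights=np.array([2.0]), bias=-1.0, kind="logreg", trained_on_n=1
        )
        mask = predict_mask(model, self._features(np.full((6, 1), 0.9), 2, 3))
        assert (mask.values == 1).all()

    def test_dimension_mismatch_reported(self):
        model = LinearClassifier(
            weights=np.ones(4), bias=0.0, kind="svm", trained_on_n=4
        )
        with pytest.raises(DimensionError, match="4"):
            predict_mask(model, self._features(np.zeros((4, 2)), 2, 2))


class TestValidationAccuracy:
    def test_constant_model_on_balanced_set(self):
        model = LinearClassifier(
            weights=np.zeros(2), bias=-1.0, kind="svm", trained_on_n=2
        )
        ds = make_ds(np.random.default_rng(0).random((40, 2)), np.repeat([0, 1], 20))
        assert validation_accuracy(model, ds) == 0.5


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        model = LinearClassifier(
            weights=np.array([0.5, -1.25]), bias=0.75, kind="logreg",
            trained_on_n=2, hyperparams={"C": 1000.0},
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LinearClassifier.from_json(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.bias == model.bias
        assert back.kind == "logreg"
        x = np.random.default_rng(1).random((20, 2))
        np.testing.assert_array_equal(back.predict(x), model.predict(x))
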