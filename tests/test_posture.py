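"""Stacked-LSTM posture classifier, statistical features, and baselines.

Training tests use a two-class toy problem (Lie vs Walk) at reduced epoch
counts — the signal templates are separable by construction, so a few
epochs suffice and keep the suite fast.  Architecture and hyperparameter
defaults are asserted separately.
"""

import numpy as np
import pytest

from caniscope.events import Posture, Sensor
from caniscope.posture import (
    BODY_CLASSES,
    ClassifierConfig,
    HEAD_CLASSES,
    TrainingConfig,
    build_model,
    extract_features,
    load_model,
    predict,
    save_model,
    train,
    train_baseline,
)
from caniscope.simulate import make_training_set

TOY_CLASSES = (Posture.WALK, Posture.LIE)


def toy_data(n_per_class=50, seed=0):
    """Separable two-class windows drawn from the body-sensor templates."""
    X, labels, _ = make_training_set(Sensor.BODY, n_per_class, seed=seed)
    keep = [i for i, l in enumerate(labels) if l in TOY_CLASSES]
    return X[keep], [labels[i] for i in keep]


def toy_model():
    return build_model(ClassifierConfig(sensor=Sensor.BODY, classes=TOY_CLASSES))


class TestBuildModel:
    def test_head_output_dimension(self):
        model = build_model(ClassifierConfig(sensor=Sensor.HEAD))
        assert model.config.n_classes == 3
        assert model.config.classes == HEAD_CLASSES

    def test_body_output_dimension(self):
        model = build_model(ClassifierConfig(sensor=Sensor.BODY))
        assert model.config.n_classes == 6
        assert model.config.classes == BODY_CLASSES

    def test_default_architecture(self):
        cfg = ClassifierConfig(sensor=Sensor.BODY)
        assert (cfg.recurrent_layers, cfg.units_per_layer) == (2, 64)
        assert (cfg.timesteps, cfg.features) == (50, 3)

    def test_zero_units_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(sensor=Sensor.BODY, units_per_layer=0)

    def test_default_training_hyperparameters(self):
        tc = TrainingConfig()
        assert (tc.beta1, tc.beta2) == (0.9, 0.999)
        assert tc.learning_rate == 0.0025
        assert (tc.batch_size, tc.epochs, tc.folds) == (25, 50, 5)

    def test_invalid_sensor_class_rejected(self):
        with pytest.raises(ValueError, match="invalid for sensor"):
            ClassifierConfig(sensor=Sensor.HEAD, classes=(Posture.WALK, Posture.LIE))


class TestTrain:
    def test_separable_toy_reaches_high_fold_f1(self):
        X, labels = toy_data()
        tc = TrainingConfig(epochs=6, folds=5, seed=0)
        model, fold_reports = train(toy_model(), X, labels, tc)
        assert len(fold_reports) == 5
        for report in fold_reports:
            assert report.macro["f1"] >= 0.95

    def test_single_class_rejected(self):
        X, labels = toy_data(n_per_class=10)
        only_walk = [i for i, l in enumerate(labels) if l is Posture.WALK]
        with pytest.raises(ValueError, match="absent"):
            train(toy_model(), X[only_walk], [labels[i] for i in only_walk],
                  TrainingConfig(epochs=1))

    def test_same_seed_identical_fold_metrics(self):
        X, labels = toy_data(n_per_class=20)
        tc = TrainingConfig(epochs=1, folds=2, seed=5)
        _, reports_a = train(toy_model(), X, labels, tc)
        _, reports_b = train(toy_model(), X, labels, tc)
        assert [r.to_dict() for r in reports_a] == [r.to_dict() for r in reports_b]

    def test_same_seed_bitwise_identical_weights(self):
        X, labels = toy_data(n_per_class=10)
        tc = TrainingConfig(epochs=1, seed=9)
        model_a = toy_model().fit(X, labels, tc)
        model_b = toy_model().fit(X, labels, tc)
        for key in model_a.params:
            assert np.array_equal(model_a.params[key], model_b.params[key])


@pytest.fixture(scope="module")
def fitted():
    X, labels = toy_data()
    return toy_model().fit(X, labels, TrainingConfig(epochs=6, seed=0))


class TestPredict:
    def test_distribution_sums_to_one(self, fitted):
        rng = np.random.default_rng(0)
        probs = fitted.predict_proba(rng.uniform(size=(4, 50, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_template_window_recovers_label(self, fitted):
        X, labels = toy_data(n_per_class=5, seed=99)
        event, dist = predict(fitted, X[0], "dog-1", 3.0)
        assert event.posture is labels[0]
        assert event.t == 3.0 and event.sensor_id is Sensor.BODY
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-6)

    def test_unnormalized_window_warns_and_clips(self, fitted):
        window = np.full((50, 3), 2.0)
        with pytest.warns(UserWarning, match="clipping"):
            event, _ = predict(fitted, window, "dog-1", 0.0)
        assert event.posture in TOY_CLASSES

    def test_tie_breaks_to_lowest_ordered_class(self, fitted):
        # force an exact tie by zeroing the output layer
        model = toy_model()
        model.initialize(np.random.default_rng(0))
        model.params["Wy"][:] = 0.0
        model.params["by"][:] = 0.0
        event, dist = predict(model, np.full((50, 3), 0.5), "d", 0.0)
        assert len(set(dist.values())) == 1  # exact tie
        assert event.posture is TOY_CLASSES[0]

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        path = tmp_path / "model.npz"
        save_model(fitted, path)
        back = load_model(path)
        assert back.config == fitted.config
        X, _ = toy_data(n_per_class=3, seed=123)
        assert np.allclose(back.predict_proba(X), fitted.predict_proba(X))


class TestExtractFeatures:
    def test_constant_window(self):
        feats = extract_features(np.full((50, 3), 2.5))
        for axis in range(3):
            mn, mx, mean, std = feats[axis * 4 : axis * 4 + 4]
            assert (mn, mx, mean, std) == (2.5, 2.5, 2.5, 0.0)

    def test_alternating_axis(self):
        window = np.zeros((50, 3))
        window[::2, 0] = 1.0
        mn, mx, mean, _ = extract_features(window)[:4]
        assert (mn, mx, mean) == (0.0, 1.0, 0.5)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        window = rng.normal(size=(50, 3))
        feats = extract_features(window)
        for axis in range(3):
            v = [window[i, axis] for i in range(50)]
            mean = sum(v) / len(v)
            var = sum((x - mean) ** 2 for x in v) / len(v)
            expected = [min(v), max(v), mean, var**0.5]
            assert np.allclose(feats[axis * 4 : axis * 4 + 4], expected)

    def test_feature_invariants(self):
        rng = np.random.default_rng(12)
        feats = extract_features(rng.normal(size=(50, 3)))
        for axis in range(3):
            mn, mx, mean, std = feats[axis * 4 : axis * 4 + 4]
            assert mn <= mean <= mx and std >= 0


class TestBaselines:
    @pytest.mark.parametrize("kind", ["svm", "naive_bayes", "decision_tree"])
    def test_separable_toy_high_accuracy(self, kind):
        X, labels = toy_data()
        feats = np.stack([extract_features(w) for w in X])
        model = train_baseline(feats, labels, kind=kind, seed=0)
        acc = np.mean(model.predict(feats) == [l.value for l in labels])
        assert acc >= 0.9

    def test_single_class_rejected(self):
        X = np.zeros((5, 12))
        with pytest.raises(ValueError, match="two classes"):
            train_baseline(X, [Posture.WALK] * 5, kind="svm")

    def test_same_seed_identical_decisions(self):
        X, labels = toy_data(n_per_class=20)
        feats = np.stack([extract_features(w) for w in X])
        a = train_baseline(feats, labels, kind="decision_tree", seed=3)
        b = train_baseline(feats, labels, kind="decision_tree", seed=3)
        assert np.array_equal(a.predict(feats), b.predict(feats))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            train_baseline(np.zeros((4, 12)), [Posture.WALK, Posture.LIE] * 2, kind="mlp")
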