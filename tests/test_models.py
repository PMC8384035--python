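"""Estimator behaviour: classifier, predictor, input assembly, fine-tuning."""

import numpy as np
import pytest
from sklearn.base import clone

from myogait import evaluation, models
from myogait.models import (
    AnkleAnglePredictor,
    GaitPhaseClassifier,
    assemble_predictor_inputs,
    classify,
    fine_tune,
    predict_ahead,
    train_angle_predictor,
    train_phase_classifier,
)

FAST = dict(epochs=3, sequence_len=6, stride=3)


@pytest.fixture(scope="module")
def trained_clf(frame_short):
    return train_phase_classifier(frame_short, epochs=8, seed=0)


class TestGaitPhaseClassifier:
    def test_sklearn_params_roundtrip(self):
        clf = GaitPhaseClassifier(epochs=5, seed=3)
        assert clone(clf).get_params() == clf.get_params()

    def test_probabilities_sum_to_one(self, trained_clf, frame_short):
        _, proba = classify(trained_clf, frame_short)
        assert proba.shape == (len(frame_short), 4)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_missing_class_listed_in_error(self, frame_short):
        bad = frame_short.slice(0, 50)
        bad.phase = np.zeros(50, dtype=np.int8)  # only IC present
        with pytest.raises(ValueError, match="FF"):
            train_phase_classifier(bad, **FAST)

    def test_training_accuracy_at_least_heldout(self, trained_clf, frame_short):
        n = len(frame_short)
        cut = int(0.8 * n)
        tr, te = frame_short.slice(0, cut), frame_short.slice(cut, n)
        acc_tr = np.mean(trained_clf.predict(tr.X) == tr.phase)
        acc_te = np.mean(trained_clf.predict(te.X) == te.phase)
        assert acc_tr >= acc_te - 0.02  # optimism up to noise

    def test_constant_features_give_valid_fixed_output(self, trained_clf):
        X = np.zeros((20, trained_clf._input_dim_))
        proba = trained_clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert len(np.unique(trained_clf.predict(X)[5:])) == 1

    def test_short_sequence_still_labels_every_window(self, trained_clf, frame_short):
        short = frame_short.slice(0, 4)  # shorter than sequence_len
        labels, proba = classify(trained_clf, short)
        assert len(labels) == 4 and proba.shape == (4, 4)

    def test_dimension_mismatch_rejected(self, trained_clf):
        with pytest.raises(ValueError, match="dimension"):
            trained_clf.predict(np.zeros((10, 3)))

    def test_fixed_seed_fit_reproducible(self, frame_short):
        a = train_phase_classifier(frame_short, seed=5, **FAST)
        b = train_phase_classifier(frame_short, seed=5, **FAST)
        assert all(
            np.array_equal(x, y)
            for x, y in zip(a.net_.get_weights(), b.net_.get_weights())
        )

    def test_loss_decreases_over_training(self, trained_clf):
        hist = trained_clf.history_["train_loss"]
        assert hist[-1] < hist[0]

    def test_shuffled_labels_no_better_than_priors(self, frame_short):
        """With shuffled labels there is no signal left: held-out accuracy
        cannot beat the majority-class rate by more than noise. (Phases are
        imbalanced -- FF fills ~35% of the cycle -- so the no-signal baseline
        is the class prior, not 1/4.)"""
        rng = np.random.default_rng(0)
        n = len(frame_short)
        cut = int(0.8 * n)
        tr = frame_short.slice(0, cut)
        te = frame_short.slice(cut, n)
        y_shuffled = rng.permutation(tr.phase)
        clf = GaitPhaseClassifier(epochs=5, seed=0)
        clf.fit(tr.X, y_shuffled)
        acc = np.mean(clf.predict(te.X) == te.phase)
        majority = np.bincount(te.phase, minlength=4).max() / len(te.phase)
        assert acc <= majority + 0.10
        assert acc < 0.60  # far below the >0.9 reached with true labels


class TestAssembleInputs:
    def test_column_counts_per_mode(self, frame_short):
        n_feat = frame_short.X.shape[1]
        assert assemble_predictor_inputs(frame_short, "angle_only").shape[1] == 1
        assert assemble_predictor_inputs(frame_short, "emg_based").shape[1] == n_feat + 1
        assert (
            assemble_predictor_inputs(frame_short, "emg_phase_based").shape[1]
            == n_feat + 5
        )
        assert (
            assemble_predictor_inputs(
                frame_short, "emg_phase_based", phase_encoding="ordinal"
            ).shape[1]
            == n_feat + 2
        )

    def test_unknown_mode_rejected(self, frame_short):
        with pytest.raises(ValueError):
            assemble_predictor_inputs(frame_short, "everything")


class TestAnkleAnglePredictor:
    def test_copy_task_identity(self, frame_short):
        """Zero horizon with angle-only input is a copy task: near-zero error."""
        frame = frame_short
        X = frame.angle_now[:, None]
        y = frame.angle_now.copy()
        reg = AnkleAnglePredictor(
            input_mode="angle_only", horizon_ms=0.0, epochs=150, lr=5e-3,
            patience=30, seed=0,
        )
        reg.fit(X, y)
        err = evaluation.rmse(reg.predict(X), y)
        assert err < 0.5

    def test_predictions_within_sane_range(self, frame_short):
        reg = train_angle_predictor(frame_short, "emg_phase_based", epochs=5, seed=0)
        yhat = predict_ahead(reg, frame_short, "true_labels")
        lo, hi = frame_short.angle_future.min(), frame_short.angle_future.max()
        assert np.all(np.isfinite(yhat))
        assert yhat.min() > lo - 10 and yhat.max() < hi + 10
        assert len(yhat) == len(frame_short)

    def test_missing_targets_rejected(self, frame_short):
        broken = frame_short.slice(0, 50)
        broken.angle_future = broken.angle_future[:10]
        with pytest.raises(ValueError, match="angle_future"):
            train_angle_predictor(broken, "angle_only", **FAST)

    def test_classifier_source_requires_classifier(self, frame_short):
        reg = train_angle_predictor(frame_short, "emg_phase_based", **FAST)
        with pytest.raises(ValueError, match="classifier"):
            predict_ahead(reg, frame_short, "classifier")

    def test_perfect_classifier_matches_true_labels(self, frame_short):
        """A classifier that reproduces the true labels yields exactly the
        same predictions as feeding the labels directly."""

        class PerfectClassifier:
            def __init__(self, truth):
                self.truth = np.asarray(truth)

            def predict(self, X):
                return self.truth[: len(X)]

        reg = train_angle_predictor(frame_short, "emg_phase_based", epochs=5, seed=0)
        oracle = PerfectClassifier(frame_short.phase)
        y_true = predict_ahead(reg, frame_short, "true_labels")
        y_clf = predict_ahead(reg, frame_short, "classifier", oracle)
        assert np.allclose(y_true, y_clf)


class TestFineTune:
    def test_zero_budget_returns_unadapted_model(self, frame_short):
        clf = train_phase_classifier(frame_short, **FAST)
        X, y = frame_short.X, frame_short.phase
        ms, curve, (X_test, y_test) = fine_tune(
            clf, X, y, minutes=[0.0, 0.1], windows_per_min=100.0,
            epochs=2, metric_fn=lambda m, a, b: np.mean(m.predict(a) == b),
        )
        assert ms[0] is clf
        base_acc = np.mean(clf.predict(X_test) == y_test)
        assert curve[0] == pytest.approx(base_acc)

    def test_budget_exceeding_data_rejected(self, frame_short):
        clf = train_phase_classifier(frame_short, **FAST)
        with pytest.raises(ValueError, match="exceeds"):
            fine_tune(clf, frame_short.X, frame_short.phase, minutes=[99.0])

    def test_same_condition_adaptation_is_benign(self, frame_short):
        """Fine-tuning on data from the unchanged condition moves accuracy
        by at most a couple of points (nothing to learn)."""
        n = len(frame_short)
        cut = n // 2
        tr = frame_short.slice(0, cut)
        rest = frame_short.slice(cut, n)
        clf = train_phase_classifier(tr, epochs=8, seed=0)
        _, curve, _ = fine_tune(
            clf, rest.X, rest.phase, minutes=[0.0, 0.05], windows_per_min=2000.0,
            epochs=4, metric_fn=lambda m, a, b: np.mean(m.predict(a) == b),
        )
        assert abs(curve[1] - curve[0]) < 0.02 + 0.02

    def test_copy_fitted_is_independent(self, frame_short):
        clf = train_phase_classifier(frame_short, **FAST)
        twin = clf.copy_fitted()
        before = clf.net_.get_weights()
        twin.continue_fit(frame_short.X, frame_short.phase, epochs=1)
        assert all(
            np.array_equal(a, b) for a, b in zip(clf.net_.get_weights(), before)
        )
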