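"""Logistic models, leave-one-out validation, and the small-sample metric suite."""

import numpy as np
import pandas as pd
import pytest

from mcdt.classify import (
    ModelSpec,
    binary_metrics,
    confusion_matrix,
    confusion_row_percent,
    fit_logistic,
    loocv_predict,
    multiclass_metrics,
)


def _clusters(rng, n_per=20, gap=10.0):
    x = np.concatenate([rng.normal(0, 1, n_per), rng.normal(gap, 1, n_per)])
    y = np.array(["OA"] * n_per + ["MCI"] * n_per)
    return x.reshape(-1, 1), y


class TestFitLogistic:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((10, 1)), np.array(["OA"] * 10))

    def test_separated_clusters_fit_perfectly(self, rng):
        X, y = _clusters(rng)
        model = fit_logistic(X, y)
        assert (model.predict(X) == y).all()

    def test_row_duplication_leaves_probabilities_unchanged(self, rng):
        X, y = _clusters(rng, n_per=15, gap=2.0)
        m1 = fit_logistic(X, y)
        m2 = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.predict_proba(X), m2.predict_proba(X), atol=1e-4)


class TestLoocv:
    def test_one_prediction_per_subject(self, rng):
        X, y = _clusters(rng, n_per=22)
        preds = loocv_predict(X, y)
        assert len(preds) == 44

    def test_perfect_separation_gives_full_accuracy(self, rng):
        X, y = _clusters(rng, n_per=20, gap=10.0)
        preds = loocv_predict(X, y)
        assert (np.array(preds) == y).mean() == 1.0

    def test_noise_predictors_score_at_chance(self, rng):
        """Label-independent predictors: LOOCV accuracy sits at the 1/3
        chance level of three balanced classes, within sampling error."""
        n = 300
        X = rng.normal(size=(n, 3))
        y = np.array((["OA", "SCI", "MCI"] * (n // 3)))
        spec = ModelSpec(outcome="ternary")
        acc = (np.array(loocv_predict(X, y, spec)) == y).mean()
        assert abs(acc - 1 / 3) < 0.09  # ~3 binomial SDs

    def test_zero_column_does_not_change_predictions(self, rng):
        X, y = _clusters(rng, n_per=12, gap=3.0)
        p1 = loocv_predict(X, y)
        p2 = loocv_predict(np.hstack([X, np.zeros_like(X)]), y)
        assert p1 == p2

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            loocv_predict(np.zeros((3, 1)), np.array(["OA", "MCI", "OA"]))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = ["OA", "SCI", "MCI", "MCI"]
        m = confusion_matrix(y, y)
        assert np.trace(m.to_numpy()) == 4
        assert m.to_numpy().sum() == 4

    def test_empty_input_zero_matrix(self):
        assert confusion_matrix([], []).to_numpy().sum() == 0

    def test_all_oa_predicted_sci(self):
        m = confusion_matrix(["OA"] * 3, ["SCI"] * 3)
        assert list(m.loc["OA"]) == [0, 3, 0]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["OA"], ["AD"])

    def test_row_percent(self):
        m = confusion_matrix(["OA", "OA", "MCI", "MCI"], ["OA", "MCI", "MCI", "MCI"])
        rp = confusion_row_percent(m)
        assert rp.loc["OA", "OA"] == 50.0
        assert rp.loc["MCI", "MCI"] == 100.0


class TestBinaryMetrics:
    def test_identity_confusion_all_100(self):
        m = pd.DataFrame([[10, 0], [0, 17]], index=["OA", "MCI"], columns=["OA", "MCI"])
        out = binary_metrics(m)
        assert out["sensitivity"] == out["specificity"] == out["accuracy"] == 100.0

    def test_study_shaped_confusion(self):
        """TP=15 FN=2 TN=8 FP=2 on a 17 MCI / 10 OA split: sensitivity 88%,
        specificity 80%, accuracy 85% after integer rounding."""
        m = pd.DataFrame([[8, 2], [2, 15]], index=["OA", "MCI"], columns=["OA", "MCI"])
        out = binary_metrics(m)
        assert round(out["sensitivity"]) == 88
        assert round(out["specificity"]) == 80
        assert round(out["accuracy"]) == 85

    def test_degenerate_all_positive_predictions(self):
        m = pd.DataFrame([[0, 10], [0, 17]], index=["OA", "MCI"], columns=["OA", "MCI"])
        out = binary_metrics(m)
        assert out["sensitivity"] == 100.0
        assert out["specificity"] == 0.0
        assert round(out["accuracy"]) == 63

    def test_empty_confusion_rejected(self):
        m = pd.DataFrame(np.zeros((2, 2), int), index=["OA", "MCI"], columns=["OA", "MCI"])
        with pytest.raises(ValueError):
            binary_metrics(m)


class TestMulticlassMetrics:
    def test_identity_confusion_all_100(self):
        m = pd.DataFrame(np.diag([10, 17, 17]), index=["OA", "SCI", "MCI"], columns=["OA", "SCI", "MCI"])
        out = multiclass_metrics(m)
        assert out["overall_accuracy"] == 100.0
        assert out["weighted_recall"] == out["weighted_precision"] == out["weighted_f1"] == 100.0

    def test_constructed_cohort_confusion(self):
        """Diagonal (8, 12, 14) with supports (10, 17, 17): overall accuracy
        34/44 = 77% after rounding."""
        m = pd.DataFrame(
            [[8, 2, 0], [3, 12, 2], [0, 3, 14]],
            index=["OA", "SCI", "MCI"], columns=["OA", "SCI", "MCI"],
        )
        out = multiclass_metrics(m)
        assert round(out["overall_accuracy"]) == 77
        assert out["per_class"]["MCI"]["recall"] == pytest.approx(100 * 14 / 17)

    def test_weighted_recall_is_overall_accuracy(self, rng):
        """Algebraic identity, checked over random confusion matrices."""
        for _ in range(200):
            counts = rng.integers(0, 30, size=(3, 3))
            if counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
                continue
            m = pd.DataFrame(counts, index=["OA", "SCI", "MCI"], columns=["OA", "SCI", "MCI"])
            out = multiclass_metrics(m)
            assert out["weighted_recall"] == pytest.approx(out["overall_accuracy"])

    def test_empty_class_warns_and_uses_remaining_support(self):
        m = pd.DataFrame(
            [[5, 0, 0], [0, 0, 0], [0, 0, 7]],
            index=["OA", "SCI", "MCI"], columns=["OA", "SCI", "MCI"],
        )
        with pytest.warns(UserWarning):
            out = multiclass_metrics(m)
        assert out["weighted_recall"] == pytest.approx(100.0)

    def test_against_reference_implementation(self, rng):
        """Cross-check the hand-rolled metric suite against scikit-learn."""
        from sklearn.metrics import f1_score, precision_score, recall_score

        y_true = rng.choice(["OA", "SCI", "MCI"], size=120)
        y_pred = rng.choice(["OA", "SCI", "MCI"], size=120)
        m = confusion_matrix(y_true, y_pred)
        out = multiclass_metrics(m)
        assert out["weighted_recall"] == pytest.approx(
            100 * recall_score(y_true, y_pred, average="weighted"), abs=1e-9
        )
        assert out["weighted_precision"] == pytest.approx(
            100 * precision_score(y_true, y_pred, average="weighted"), abs=1e-9
        )
        assert out["weighted_f1"] == pytest.approx(
            100 * f1_score(y_true, y_pred, average="weighted"), abs=1e-9
        )
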