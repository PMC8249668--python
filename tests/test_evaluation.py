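"""Prevalence-weighted metrics and the split/cross-validation protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sentweet.evaluation import (
    ConfusionMatrix,
    accuracy,
    cross_validate,
    evaluate_predictions,
    f1_score,
    fine_tune,
    run_experiment,
    stratified_split,
    weighted_f1,
    weighted_precision,
    weighted_recall,
)

WORKED = ConfusionMatrix(np.array([[8, 1, 1], [2, 2, 1], [1, 1, 3]]))


class TestWeightedRecall:
    def test_diagonal_matrix_is_perfect(self):
        assert weighted_recall(ConfusionMatrix(np.diag([5, 3, 2]))) == 1.0

    def test_worked_example(self):
        # (10/20)(8/10) + (5/20)(2/5) + (5/20)(3/5)
        assert weighted_recall(WORKED) == pytest.approx(0.65)

    def test_single_class_predictor_recovers_prevalence(self):
        cm = ConfusionMatrix(np.array([[10, 0, 0], [5, 0, 0], [5, 0, 0]]))
        assert weighted_recall(cm) == pytest.approx(10 / 20)

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            weighted_recall(ConfusionMatrix(np.zeros((3, 3), dtype=int)))


class TestWeightedPrecision:
    def test_diagonal_matrix_is_perfect(self):
        assert weighted_precision(ConfusionMatrix(np.diag([5, 3, 2]))) == 1.0

    def test_worked_example(self):
        # (10/20)(8/11) + (5/20)(2/4) + (5/20)(3/5)
        expected = 0.5 * 8 / 11 + 0.25 * 0.5 + 0.25 * 0.6
        assert weighted_precision(WORKED) == pytest.approx(expected)
        assert weighted_precision(WORKED) == pytest.approx(0.6386, abs=5e-5)

    def test_single_class_predictor_keeps_only_its_purity_term(self):
        cm = ConfusionMatrix(np.array([[10, 0, 0], [5, 0, 0], [5, 0, 0]]))
        assert weighted_precision(cm) == pytest.approx((10 / 20) * (10 / 20))


class TestF1:
    @pytest.mark.parametrize("p,r,expected", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5), (0.0, 0.0, 0.0)])
    def test_fixed_points(self, p, r, expected):
        assert f1_score(p, r) == expected

    def test_worked_example(self):
        p, r = weighted_precision(WORKED), weighted_recall(WORKED)
        assert f1_score(p, r) == pytest.approx(0.6443, abs=5e-5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_harmonic_bounded_by_arithmetic_mean(self, p, r):
        assert f1_score(p, r) <= (p + r) / 2 + 1e-12


@st.composite
def confusion_matrices(draw):
    counts = draw(
        st.lists(st.integers(0, 40), min_size=9, max_size=9).filter(lambda c: sum(c) > 0)
    )
    return ConfusionMatrix(np.array(counts).reshape(3, 3))


@given(confusion_matrices())
@settings(max_examples=150, deadline=None)
def test_weighted_recall_equals_accuracy(cm):
    """Algebraic identity: sum_s (n_s/N)(TP_s/n_s) = trace/N."""
    assert weighted_recall(cm) == pytest.approx(accuracy(cm))


@given(confusion_matrices(), st.permutations([0, 1, 2]))
@settings(max_examples=100, deadline=None)
def test_metrics_invariant_under_class_permutation(cm, perm):
    permuted = ConfusionMatrix(cm.counts[np.ix_(perm, perm)])
    assert weighted_precision(permuted) == pytest.approx(weighted_precision(cm))
    assert weighted_recall(permuted) == pytest.approx(weighted_recall(cm))


@given(confusion_matrices())
@settings(max_examples=100, deadline=None)
def test_metrics_stay_in_unit_interval(cm):
    for value in (weighted_precision(cm), weighted_recall(cm), accuracy(cm)):
        assert 0.0 <= value <= 1.0


def test_confusion_matrix_from_labels_and_frame():
    cm = ConfusionMatrix.from_labels(
        ["positive", "negative", "neutral", "positive"],
        ["positive", "neutral", "neutral", "negative"],
    )
    assert cm.total == 4
    assert cm.counts[0, 0] == 1 and cm.counts[1, 2] == 1
    frame = cm.to_frame()
    assert list(frame.index) == ["positive", "negative", "neutral"]


def test_evaluate_predictions_perfect():
    gold = ["positive"] * 3 + ["negative"] * 2 + ["neutral"] * 2
    report = evaluate_predictions(gold, gold)
    assert report.f1 == pytest.approx(1.0) and report.accuracy == 1.0


class TestProtocol:
    def test_split_sizes_are_80_20(self):
        y = np.array(["positive"] * 470 + ["negative"] * 170 + ["neutral"] * 360)
        X = np.zeros((1000, 2))
        X_tr, X_te, y_tr, y_te = stratified_split(X, y, seed=0)
        assert len(y_tr) == 800 and len(y_te) == 200

    @pytest.mark.parametrize("seed", range(20))
    def test_split_preserves_priors_within_two_points(self, seed):
        y = np.array(["positive"] * 470 + ["negative"] * 170 + ["neutral"] * 360)
        X = np.zeros((1000, 2))
        _, _, y_tr, y_te = stratified_split(X, y, seed=seed)
        for labels in (y_tr, y_te):
            for cls, prior in zip(("positive", "negative", "neutral"), (0.47, 0.17, 0.36)):
                assert abs((labels == cls).mean() - prior) <= 0.02

    def test_missing_class_raises(self):
        y = np.array(["positive"] * 10)
        with pytest.raises(ValueError):
            stratified_split(np.zeros((10, 2)), y, seed=0)

    def test_zero_epoch_fine_tune_is_identity(self, small_embeddings):
        from sentweet.models import NeuralTweetClassifier

        X, y = small_embeddings
        clf = NeuralTweetClassifier("FFNN", [16], epochs=2, batch_size=30, seed=0).fit(X, y)
        tuned = fine_tune(clf, X, y, epochs=0)
        assert np.allclose(tuned.predict_proba(X), clf.predict_proba(X))

    def test_fine_tune_continues_training(self, small_embeddings):
        from sentweet.models import NeuralTweetClassifier

        X, y = small_embeddings
        clf = NeuralTweetClassifier("FFNN", [16], epochs=2, batch_size=30, seed=0).fit(X, y)
        tuned = fine_tune(clf, X, y, epochs=2)
        assert len(tuned.history_) == 4
        assert not np.allclose(tuned.predict_proba(X), clf.predict_proba(X))

    def test_run_experiment_reports_all_models(self, small_embeddings):
        from sentweet.models import NeuralTweetClassifier

        X, y = small_embeddings
        table = run_experiment(
            {
                "ffnn": NeuralTweetClassifier("FFNN", [16], epochs=2, batch_size=30),
                "cnn": NeuralTweetClassifier("CNN1", [1, 2], epochs=2, batch_size=30),
            },
            X,
            y,
            seed=1,
        )
        assert set(table.index) == {"ffnn", "cnn"}
        assert set(table.columns) >= {"precision_w", "recall_w", "f1", "accuracy"}
        assert ((table["f1"] >= 0) & (table["f1"] <= 1)).all()

    def test_cross_validate_returns_fold_scores(self, small_embeddings):
        from sentweet.models import NeuralTweetClassifier

        X, y = small_embeddings
        scores = cross_validate(
            NeuralTweetClassifier("FFNN", [8], epochs=1, batch_size=30),
            X, y, n_splits=3, seed=0,
        )
        assert len(scores) == 3
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_weighted_f1_wrapper(self):
        gold = ["positive", "negative", "neutral"]
        assert weighted_f1(gold, gold) == 1.0
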