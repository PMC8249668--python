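"""Prevalence-weighted evaluation metrics and the experiment protocol.

The three-class metrics weight each class's precision/recall by its share of
the evaluation set (n_s / N) and combine them with the harmonic mean:

    precision = sum_s (n_s / N) * TP_s / (TP_s + FP_s)
    recall    = sum_s (n_s / N) * TP_s / (TP_s + FN_s)
    F1        = 2 * precision * recall / (precision + recall)

With these definitions weighted recall equals plain accuracy algebraically
(sum_s n_s/N * TP_s/n_s = trace/N), which is asserted as a cross-check.

The experiment protocol is a stratified 80/20 train/test split, optional
10-fold cross-validation inside the training portion, and an optional
pre-train-then-fine-tune regime where a model fitted on a source corpus
continues training on the target corpus.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .types import LABELS


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = gold class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @classmethod
    def from_labels(cls, gold, predicted, class_order: tuple[str, ...] = LABELS):
        index = {c: i for i, c in enumerate(class_order)}
        counts = np.zeros((len(class_order), len(class_order)), dtype=int)
        for g, p in zip(gold, predicted):
            counts[index[g], index[p]] += 1
        return cls(counts, class_order)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


def weighted_recall(cm: ConfusionMatrix) -> float:
    """Prevalence-weighted recall; classes absent from the gold set contribute 0."""
    counts = cm.counts
    N = counts.sum()
    if N == 0:
        raise ValueError("empty confusion matrix")
    value = 0.0
    for s in range(counts.shape[0]):
        n_s = counts[s].sum()
        if n_s == 0:
            continue
        tp = counts[s, s]
        value += (n_s / N) * (tp / n_s)  # TP / (TP + FN), and TP + FN = n_s
    return float(value)


def weighted_precision(cm: ConfusionMatrix) -> float:
    """Prevalence-weighted precision; a class never predicted contributes 0."""
    counts = cm.counts
    N = counts.sum()
    if N == 0:
        raise ValueError("empty confusion matrix")
    value = 0.0
    for s in range(counts.shape[0]):
        n_s = counts[s].sum()
        predicted_s = counts[:, s].sum()
        if n_s == 0 or predicted_s == 0:
            continue
        value += (n_s / N) * (counts[s, s] / predicted_s)
    return float(value)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def accuracy(cm: ConfusionMatrix) -> float:
    N = cm.total
    if N == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / N)


@dataclass
class MetricReport:
    precision_w: float
    recall_w: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision_w": self.precision_w,
            "recall_w": self.recall_w,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


def evaluate_predictions(gold, predicted, class_order: tuple[str, ...] = LABELS) -> MetricReport:
    cm = ConfusionMatrix.from_labels(gold, predicted, class_order)
    p = weighted_precision(cm)
    r = weighted_recall(cm)
    return MetricReport(precision_w=p, recall_w=r, f1=f1_score(p, r), accuracy=accuracy(cm))


def weighted_f1(gold, predicted, class_order: tuple[str, ...] = LABELS) -> float:
    return evaluate_predictions(gold, predicted, class_order).f1


def stratified_split(X, y, test_size: float = 0.2, seed: int = 0):
    """Stratified train/test split (default 80/20) preserving class priors."""
    classes, counts = np.unique(np.asarray(y), return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("stratification needs >= 2 classes with >= 2 members each")
    return train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )


def cross_validate(estimator, X, y, n_splits: int = 10, seed: int = 0) -> list[float]:
    """Stratified k-fold cross-validation returning per-fold weighted F1."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        est = copy.deepcopy(estimator)
        est.fit(X[train_idx], y[train_idx])
        scores.append(weighted_f1(y[val_idx], est.predict(X[val_idx])))
    return scores


def fine_tune(fitted_estimator, X, y, epochs: int | None = None):
    """Continue training a fitted classifier on a target corpus.

    With ``epochs=0`` the model is returned unchanged (source-only).  The
    estimator must expose ``partial_fit_epochs`` (the neural classifiers do).
    """
    est = copy.deepcopy(fitted_estimator)
    if epochs == 0:
        return est
    est.partial_fit_epochs(X, y, epochs=epochs)
    return est


def run_experiment(
    estimators: dict[str, object],
    X,
    y,
    test_size: float = 0.2,
    cv_folds: int | None = None,
    seed: int = 0,
    pretrained: dict[str, object] | None = None,
    fine_tune_epochs: int | None = None,
) -> pd.DataFrame:
    """Train each estimator on a stratified 80% split and report metrics on
    the untouched 20%.

    ``pretrained`` maps names to already-fitted models to be fine-tuned on the
    training split instead of trained from scratch.  When ``cv_folds`` is set,
    per-fold weighted F1 inside the training portion is reported alongside.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    X_train, X_test, y_train, y_test = stratified_split(X, y, test_size, seed)
    rows = {}
    for name, est in estimators.items():
        est = copy.deepcopy(est)
        if pretrained is not None and name in pretrained:
            est = fine_tune(pretrained[name], X_train, y_train, epochs=fine_tune_epochs)
        else:
            est.fit(X_train, y_train)
        report = evaluate_predictions(y_test, est.predict(X_test))
        row = report.as_dict()
        if cv_folds:
            row["cv_f1_mean"] = float(np.mean(cross_validate(est, X_train, y_train,
                                                             n_splits=cv_folds, seed=seed)))
        rows[name] = row
    return pd.DataFrame(rows).T
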