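"""Vote aggregation: hard/soft majority voting and the learned meta-learner.

Base classifiers each emit either a one-hot class vote ("hard") or a
probability triplet ("soft") per tweet.  Plain voting gives every model equal
influence; the meta-learner instead trains a small feed-forward network on
the flattened votes (3m features for m models) so that each model's influence
can depend on what it voted — a model that is reliable only for one class is
then trusted only there.  For the seven-model ensemble the meta-learner has
two hidden layers of 21 and 7 neurons; for other m it keeps the same
down-sampling principle (3m, then about a third of that).

Meta-learner training votes are produced out-of-fold: the base models are
refitted on k-1 folds and vote on the held-out fold, so the meta-learner
never sees votes from a model that trained on the same tweet.
"""

from __future__ import annotations

import copy
import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .models import Dense, class_weights
from .types import LABELS

#: tie-break priority over class indices (positive > neutral > negative)
TIE_ORDER = (0, 2, 1)


def _tie_argmax(scores: np.ndarray) -> int:
    """Argmax over 3 classes with ties broken by the fixed class priority."""
    best = scores.max()
    for cls in TIE_ORDER:
        if scores[cls] == best:
            return cls
    raise AssertionError("unreachable")


class VoteMatrix:
    """Per-tweet votes of m base models: an (m, 3) matrix, hard or soft."""

    def __init__(self, votes: np.ndarray, mode: str = "hard"):
        votes = np.asarray(votes, dtype=float)
        if votes.ndim != 2 or votes.shape[1] != 3:
            raise ValueError("votes must be (m, 3)")
        if mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        if mode == "hard":
            if not (np.isin(votes, (0.0, 1.0)).all() and (votes.sum(axis=1) == 1).all()):
                raise ValueError("hard votes must be one-hot rows")
        elif not np.allclose(votes.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("soft vote rows must sum to 1")
        self.votes = votes
        self.mode = mode

    @property
    def m(self) -> int:
        return self.votes.shape[0]


def majority_vote(votes: VoteMatrix, soft_votes: VoteMatrix | None = None) -> int:
    """Class with the most hard votes.

    Ties are broken by summed soft probabilities when ``soft_votes`` is
    available, otherwise by the fixed class priority positive > neutral >
    negative.
    """
    if votes.mode != "hard":
        raise ValueError("majority_vote expects hard votes")
    tally = votes.votes.sum(axis=0)
    best = tally.max()
    tied = np.flatnonzero(tally == best)
    if len(tied) == 1:
        return int(tied[0])
    if soft_votes is not None:
        sums = soft_votes.votes.sum(axis=0)
        masked = np.full(3, -np.inf)
        masked[tied] = sums[tied]
        return _tie_argmax(masked)
    masked = np.full(3, -np.inf)
    masked[tied] = tally[tied]
    return _tie_argmax(masked)


def soft_vote(votes: VoteMatrix) -> int:
    """Argmax of the column-mean probability vector, priority tie-break."""
    if votes.mode != "soft":
        raise ValueError("soft_vote expects soft votes")
    return _tie_argmax(votes.votes.mean(axis=0))


def select_models(model_scores: list[tuple[object, float]],
                  tolerance: float = 0.4) -> list[object]:
    """Keep models whose score is within ``tolerance`` below the mean score.

    Scores are on whatever scale the caller uses (the reference protocol uses
    percentage-point F1 with a 0.4 point tolerance).
    """
    if len(model_scores) < 2:
        raise ValueError("need at least two scored models")
    scores = np.array([s for _, s in model_scores], dtype=float)
    threshold = scores.mean() - tolerance
    return [m for (m, s) in model_scores if s >= threshold]


def meta_layer_widths(m: int) -> tuple[int, int]:
    """Hidden widths (3m, ceil(3m/3)) — (21, 7) for the seven-model ensemble."""
    return 3 * m, math.ceil(3 * m / 3)


def votes_from_estimators(estimators, X, mode: str = "hard") -> np.ndarray:
    """Stack base-model votes into an (N, m, 3) array."""
    per_model = []
    for est in estimators:
        probs = est.predict_proba(X)
        if mode == "hard":
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(probs)), probs.argmax(axis=1)] = 1.0
            per_model.append(onehot)
        else:
            per_model.append(probs)
    return np.stack(per_model, axis=1)


class _VotingBase(BaseEstimator, ClassifierMixin):
    def __init__(self, estimators: list | None = None, prefit: bool = True):
        self.estimators = estimators
        self.prefit = prefit

    def fit(self, X, y):
        self.classes_ = np.array(LABELS)
        if not self.prefit:
            self.estimators_ = [copy.deepcopy(e).fit(X, y) for e in self.estimators]
        else:
            self.estimators_ = list(self.estimators)
        return self

    def _check(self):
        check_is_fitted(self, "estimators_")


class MajorityVoteEnsemble(_VotingBase):
    """Hard-voting baseline over prefit (or refit) base classifiers."""

    def predict(self, X):
        self._check()
        hard = votes_from_estimators(self.estimators_, X, "hard")
        soft = votes_from_estimators(self.estimators_, X, "soft")
        out = [
            majority_vote(VoteMatrix(h, "hard"), VoteMatrix(s, "soft"))
            for h, s in zip(hard, soft)
        ]
        return self.classes_[np.array(out)]


class SoftVoteEnsemble(_VotingBase):
    """Mean-probability voting over base classifiers."""

    def predict_proba(self, X):
        self._check()
        return votes_from_estimators(self.estimators_, X, "soft").mean(axis=1)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.array([_tie_argmax(p) for p in probs])]


class _MetaFFNN:
    """The vote-aggregation network: 3m -> 3m -> ceil(m) -> 3."""

    def __init__(self, m: int, n_classes: int, rng: np.random.Generator):
        w1, w2 = meta_layer_widths(m)
        self.layers = [Dense(3 * m, w1, rng), Dense(w1, w2, rng), Dense(w2, n_classes, rng)]

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, votes_flat: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                dropout_rate: float = 0.5) -> Tensor:
        h = Tensor(votes_flat)
        for layer in self.layers[:-1]:
            h = ad.dropout(layer(h).relu(), dropout_rate, rng, train)
        return self.layers[-1](h)


class MetaLearnerEnsemble(BaseEstimator, ClassifierMixin):
    """Learned vote aggregation: an FFNN over the base models' flattened votes.

    ``fit(X, y)`` produces training votes out-of-fold via ``cv_folds``-fold
    stratified cross-validation over clones of the base estimators, then
    trains the meta network under the shared protocol (class-weighted
    cross-entropy, Adam, batch 100).  ``mode`` selects hard one-hot votes
    (default, matching the reference system) or soft probability votes.
    """

    def __init__(
        self,
        estimators: list | None = None,
        mode: str = "hard",
        cv_folds: int = 5,
        epochs: int = 40,
        batch_size: int = 100,
        lr: float = 0.001,
        dropout: float = 0.5,
        seed: int = 0,
        prefit: bool = False,
    ):
        self.estimators = estimators
        self.mode = mode
        self.cv_folds = cv_folds
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.dropout = dropout
        self.seed = seed
        self.prefit = prefit

    def _encode_y(self, y) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes_)}
        return np.array([index[v] for v in np.asarray(y)])

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.array([c for c in LABELS if c in set(y)]) if set(
            np.unique(y)
        ) <= set(LABELS) else np.unique(y)
        if self.prefit:
            self.estimators_ = list(self.estimators)
            votes = votes_from_estimators(self.estimators_, X, self.mode)
        else:
            votes = self._out_of_fold_votes(X, y)
            self.estimators_ = [copy.deepcopy(e).fit(X, y) for e in self.estimators]
        self.fit_votes(votes, y)
        return self

    def _out_of_fold_votes(self, X, y) -> np.ndarray:
        X = np.asarray(X)
        skf = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
        votes = np.zeros((len(y), len(self.estimators), 3))
        for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
            fold_models = [copy.deepcopy(e).fit(X[train_idx], y[train_idx])
                           for e in self.estimators]
            votes[val_idx] = votes_from_estimators(fold_models, X[val_idx], self.mode)
        return votes

    def fit_votes(self, votes: np.ndarray, y):
        """Train the meta network directly on an (N, m, 3) vote array."""
        votes = np.asarray(votes, dtype=float)
        if votes.ndim != 3 or votes.shape[2] != 3:
            raise ValueError("votes must be (N, m, 3)")
        if not hasattr(self, "classes_"):
            y_arr = np.asarray(y)
            self.classes_ = np.array([c for c in LABELS if c in set(y_arr)]) if set(
                np.unique(y_arr)
            ) <= set(LABELS) else np.unique(y_arr)
        y_idx = self._encode_y(y)
        self.m_ = votes.shape[1]
        n_classes = len(self.classes_)
        rng = np.random.default_rng(self.seed)
        self.meta_model_ = _MetaFFNN(self.m_, n_classes, rng)
        weights = class_weights(y_idx, n_classes)
        optimizer = Adam(self.meta_model_.parameters(), lr=self.lr)
        flat = votes.reshape(len(votes), -1)
        n = len(flat)
        self.history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                logits = self.meta_model_.forward(flat[sel], train=True, rng=rng,
                                                  dropout_rate=self.dropout)
                loss = ad.softmax_cross_entropy(logits, y_idx[sel], weights)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.data) * len(sel)
            self.history_.append(epoch_loss / n)
        return self

    def predict_proba_votes(self, votes: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "meta_model_")
        votes = np.asarray(votes, dtype=float)
        if votes.shape[1] != self.m_:
            raise ValueError(f"expected votes from {self.m_} models, got {votes.shape[1]}")
        logits = self.meta_model_.forward(votes.reshape(len(votes), -1))
        return ad.softmax(logits.data)

    def predict_votes(self, votes: np.ndarray) -> np.ndarray:
        probs = self.predict_proba_votes(votes)
        return self.classes_[probs.argmax(axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        votes = votes_from_estimators(self.estimators_, X, self.mode)
        return self.predict_proba_votes(votes)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]


__all__ = [
    "VoteMatrix",
    "majority_vote",
    "soft_vote",
    "select_models",
    "meta_layer_widths",
    "votes_from_estimators",
    "MajorityVoteEnsemble",
    "SoftVoteEnsemble",
    "MetaLearnerEnsemble",
    "TIE_ORDER",
]
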