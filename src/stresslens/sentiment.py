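"""Binary sentiment split over fused representations.

Stress analysis operates on the *negative* half of the corpus (the stress
document set DT): a logistic head over mean-pooled fused token vectors
classifies each post positive/negative, and the corpus is partitioned on
the predictions. The head is deliberately minimal — its job is to exercise
the fused features, not to compete on sentiment benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .corpus import Post
from .topic_fusion import FusedSequence

NEGATIVE, POSITIVE = "negative", "positive"


def pool(fused: FusedSequence | np.ndarray) -> np.ndarray:
    """Mean-pool token vectors into one document feature vector."""
    vectors = fused.vectors if isinstance(fused, FusedSequence) else np.asarray(fused)
    if vectors.shape[0] == 0:
        raise ValueError("cannot pool an empty sequence")
    return vectors.mean(axis=0)


@dataclass
class SentimentHyper:
    lr: float = 0.1
    epochs: int = 300
    seed: int = 0
    threshold: float = 0.5
    class_weighted: bool = False  # inverse-frequency weights for imbalance
    holdout_fraction: float = 0.2


class SentimentClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression trained by full-batch Adam.

    The decision is ``sigmoid(w·x + b) >= threshold`` → negative, i.e. the
    positive class of the logistic model is the *negative* sentiment (the
    quantity of interest downstream). Training is deterministic given the
    seed.
    """

    def __init__(
        self,
        lr: float = 0.1,
        epochs: int = 300,
        seed: int = 0,
        threshold: float = 0.5,
        class_weighted: bool = False,
    ):
        self.lr = lr
        self.epochs = epochs
        self.seed = seed
        self.threshold = threshold
        self.class_weighted = class_weighted

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "SentimentClassifier":
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        X = np.asarray(X, dtype=float)
        t = np.array([1.0 if lab == NEGATIVE else 0.0 for lab in y])
        if len(set(y)) < 2:
            raise ValueError("training set must contain both classes")
        n, d = X.shape
        if self.class_weighted:
            pos_frac = t.mean()
            sw = np.where(t == 1.0, 0.5 / pos_frac, 0.5 / (1.0 - pos_frac))
        else:
            sw = np.ones(n)
        rng = np.random.default_rng(self.seed)
        w = 0.01 * rng.standard_normal(d)
        b = 0.0
        m = np.zeros(d + 1)
        v = np.zeros(d + 1)
        b1, b2, eps = 0.9, 0.999, 1e-8
        for step in range(1, self.epochs + 1):
            p = 1.0 / (1.0 + np.exp(-(X @ w + b)))
            err = sw * (p - t) / n
            grad = np.concatenate([X.T @ err, [err.sum()]])
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad**2
            update = self.lr * (m / (1 - b1**step)) / (np.sqrt(v / (1 - b2**step)) + eps)
            w -= update[:-1]
            b -= update[-1]
        self.weight_ = w
        self.bias_ = float(b)
        self.classes_ = np.array([POSITIVE, NEGATIVE])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weight_ + self.bias_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p_neg = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p_neg, p_neg])

    def predict(self, X: np.ndarray) -> np.ndarray:
        p_neg = self.predict_proba(X)[:, 1]
        return np.where(p_neg >= self.threshold, NEGATIVE, POSITIVE)


def train_sentiment(
    train: Sequence[tuple[FusedSequence, str]],
    hyper: SentimentHyper | None = None,
) -> tuple[SentimentClassifier, float]:
    """Train the logistic head on (fused sequence, label) pairs.

    A seeded holdout split reports validation accuracy alongside the model.
    """
    hyper = hyper or SentimentHyper()
    X = np.stack([pool(seq) for seq, _ in train])
    y = [lab for _, lab in train]
    rng = np.random.default_rng(hyper.seed)
    idx = rng.permutation(len(y))
    n_hold = max(1, int(round(hyper.holdout_fraction * len(y))))
    hold, fit_idx = idx[:n_hold], idx[n_hold:]
    model = SentimentClassifier(
        lr=hyper.lr,
        epochs=hyper.epochs,
        seed=hyper.seed,
        threshold=hyper.threshold,
        class_weighted=hyper.class_weighted,
    )
    model.fit(X[fit_idx], [y[i] for i in fit_idx])
    pred = model.predict(X[hold])
    accuracy = float(np.mean([p == y[i] for p, i in zip(pred, hold)]))
    return model, accuracy


def split_corpus(
    posts: Sequence[Post],
    fused: Mapping[str, FusedSequence],
    model: SentimentClassifier,
) -> tuple[list[Post], list[Post]]:
    """Partition posts into (negative stress set DT, positive set)."""
    X = np.stack([pool(fused[p.id]) for p in posts])
    pred = model.predict(X)
    negative = [p for p, lab in zip(posts, pred) if lab == NEGATIVE]
    positive = [p for p, lab in zip(posts, pred) if lab == POSITIVE]
    assert len(negative) + len(positive) == len(posts)
    return negative, positive
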