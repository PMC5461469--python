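"""Supervised learners over molecular descriptors plus the KNN feature.

Two model families mirror the similarity-informed modeling setup:

* a shallow weighted decision tree (entropy splits, default depth 2) whose
  rule form can express "toxic iff KNN-positive, else non-toxic when bond
  polarizability is high";
* a one-hidden-layer sigmoid multilayer perceptron trained by weighted
  per-instance stochastic gradient descent with momentum. The defaults are
  pinned numerically (hidden = ceil((features + classes)/2), learning rate
  0.3, momentum 0.2, 500 epochs) so "default parameters" is reproducible
  without any external toolkit.

Class imbalance is handled by instance reweighting: every toxicant gets
weight n_negative / n_positive (2.95 for a 268/791 split), equalizing the
total class weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

try:  # optional JIT for the SGD inner loop; pure-numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "SchemaMismatchError",
    "ModelingDataset",
    "ClassWeights",
    "compute_class_weights",
    "PerceptronConfig",
    "PerceptronModel",
    "train_perceptron",
    "DecisionTreeModel",
    "train_decision_tree",
    "predict",
]


class SchemaMismatchError(ValueError):
    """Prediction input does not carry the model's feature schema."""


@dataclass
class ModelingDataset:
    """Aligned features/labels/weights (plus optional fingerprints).

    ``X`` holds the 27 descriptors and, when fused, a binary ``KNN``
    column. Fingerprints, when present, let evaluation protocols recompute
    the KNN feature against training folds only.
    """

    ids: list[str]
    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray | None = None
    fingerprints: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=bool)
        if len(self.X) != len(self.y) or len(self.ids) != len(self.y):
            raise ValueError("features, labels and ids must align")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.y):
                raise ValueError("weights must align with labels")
            if np.any(self.weights <= 0):
                raise ValueError("instance weights must be positive")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    def subset(self, idx: np.ndarray) -> "ModelingDataset":
        return ModelingDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            weights=None if self.weights is None else self.weights[idx],
            fingerprints=None if self.fingerprints is None
            else self.fingerprints[idx],
        )

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ClassWeights:
    factor: float
    weights: np.ndarray


def compute_class_weights(
    labels: np.ndarray, mode: str = "exact"
) -> ClassWeights:
    """Weight toxicants by n_negative / n_positive; non-toxicants by 1.

    ``mode="paper"`` rounds the factor to 2 decimals (e.g. 2.95 for
    268/791); ``mode="exact"`` keeps it exact so the weighted class totals
    are equal to machine precision.
    """
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute weights")
    factor = n_neg / n_pos
    if mode == "paper":
        factor = round(factor, 2)
    elif mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    weights = np.where(y, factor, 1.0)
    return ClassWeights(factor=factor, weights=weights)


# ---------------------------------------------------------------------------
# decision tree (sklearn behind the surface)


@dataclass
class DecisionTreeModel:
    feature_names: tuple[str, ...]
    tree: DecisionTreeClassifier

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise SchemaMismatchError(f"missing features: {missing}")
        return self.tree.predict(X[list(self.feature_names)].to_numpy(float)) == 1


def train_decision_tree(
    data: ModelingDataset,
    features: Sequence[str],
    *,
    max_depth: int = 2,
    seed: int = 0,
) -> DecisionTreeModel:
    """Weighted binary tree with entropy splits over the named features."""
    features = tuple(features)
    if not features:
        raise ValueError("feature list is empty")
    missing = [f for f in features if f not in data.X.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    tree = DecisionTreeClassifier(
        criterion="entropy", max_depth=max_depth, random_state=seed
    )
    tree.fit(
        data.X[list(features)].to_numpy(float),
        data.y.astype(int),
        sample_weight=data.weights,
    )
    return DecisionTreeModel(feature_names=features, tree=tree)


# ---------------------------------------------------------------------------
# multilayer perceptron


@dataclass(frozen=True)
class PerceptronConfig:
    """One-hidden-layer sigmoid network hyperparameters.

    ``hidden_units=None`` resolves to ceil((n_features + 2) / 2), the
    conventional "half of attributes plus classes" default.
    """

    hidden_units: int | None = None
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units is not None and self.hidden_units < 1:
            raise ValueError("hidden_units must be positive")
        if self.learning_rate < 0 or not 0 <= self.momentum < 1:
            raise ValueError("invalid learning rate or momentum")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def resolve_hidden(self, n_features: int) -> int:
        if self.hidden_units is not None:
            return self.hidden_units
        return math.ceil((n_features + 2) / 2)


@njit(cache=False)
def _sgd_train(X, T, w, W1, b1, W2, b2, lr, momentum, epochs):  # pragma: no cover
    n, f = X.shape
    h = W1.shape[1]
    k = W2.shape[1]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    for _ in range(epochs):
        for i in range(n):
            x = X[i]
            # forward
            a1 = np.empty(h)
            for j in range(h):
                s = b1[j]
                for p in range(f):
                    s += x[p] * W1[p, j]
                a1[j] = 1.0 / (1.0 + np.exp(-s))
            out = np.empty(k)
            for c in range(k):
                s = b2[c]
                for j in range(h):
                    s += a1[j] * W2[j, c]
                out[c] = 1.0 / (1.0 + np.exp(-s))
            # backward (squared error, sigmoid units)
            d_out = np.empty(k)
            for c in range(k):
                d_out[c] = (T[i, c] - out[c]) * out[c] * (1.0 - out[c]) * w[i]
            d_hid = np.empty(h)
            for j in range(h):
                s = 0.0
                for c in range(k):
                    s += d_out[c] * W2[j, c]
                d_hid[j] = s * a1[j] * (1.0 - a1[j])
            for c in range(k):
                for j in range(h):
                    vW2[j, c] = lr * d_out[c] * a1[j] + momentum * vW2[j, c]
                    W2[j, c] += vW2[j, c]
                vb2[c] = lr * d_out[c] + momentum * vb2[c]
                b2[c] += vb2[c]
            for j in range(h):
                for p in range(f):
                    vW1[p, j] = lr * d_hid[j] * x[p] + momentum * vW1[p, j]
                    W1[p, j] += vW1[p, j]
                vb1[j] = lr * d_hid[j] + momentum * vb1[j]
                b1[j] += vb1[j]


def _sgd_train_numpy(X, T, w, W1, b1, W2, b2, lr, momentum, epochs):
    """Pure-numpy twin of :func:`_sgd_train` (same update order)."""
    n = X.shape[0]
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)
    for _ in range(epochs):
        for i in range(n):
            x = X[i]
            a1 = 1.0 / (1.0 + np.exp(-(x @ W1 + b1)))
            out = 1.0 / (1.0 + np.exp(-(a1 @ W2 + b2)))
            d_out = (T[i] - out) * out * (1.0 - out) * w[i]
            d_hid = (W2 @ d_out) * a1 * (1.0 - a1)
            vW2 *= momentum; vW2 += lr * np.outer(a1, d_out); W2 += vW2
            vb2 *= momentum; vb2 += lr * d_out; b2 += vb2
            vW1 *= momentum; vW1 += lr * np.outer(x, d_hid); W1 += vW1
            vb1 *= momentum; vb1 += lr * d_hid; b1 += vb1


@dataclass
class PerceptronModel:
    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    config: PerceptronConfig

    def _forward(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.scale
        a1 = 1.0 / (1.0 + np.exp(-(Z @ self.W1 + self.b1)))
        return 1.0 / (1.0 + np.exp(-(a1 @ self.W2 + self.b2)))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Class with the larger output unit (column 1 = toxicant)."""
        _check_schema(self.feature_names, X)
        out = self._forward(X[list(self.feature_names)].to_numpy(float))
        return out[:, 1] > out[:, 0]


def train_perceptron(
    data: ModelingDataset, cfg: PerceptronConfig = PerceptronConfig()
) -> PerceptronModel:
    """Train the weighted sigmoid MLP; deterministic under ``cfg.seed``.

    Features are standardized to zero mean / unit variance on the training
    data; the statistics are stored with the model and reused at
    prediction time. Instances are visited in data order each epoch;
    the seed controls only the uniform(-0.5, 0.5) weight initialization.
    """
    X = data.X.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    y = data.y.astype(int)
    T = np.eye(2)[y]  # one-hot: column 1 = toxicant
    w = data.weights if data.weights is not None else np.ones(len(y))

    f = Z.shape[1]
    h = cfg.resolve_hidden(f)
    rng = np.random.default_rng(cfg.seed)
    W1 = rng.uniform(-0.5, 0.5, size=(f, h))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    W2 = rng.uniform(-0.5, 0.5, size=(h, 2))
    b2 = rng.uniform(-0.5, 0.5, size=2)

    trainer = _sgd_train if _HAVE_NUMBA else _sgd_train_numpy
    trainer(
        np.ascontiguousarray(Z), np.ascontiguousarray(T),
        np.ascontiguousarray(w, dtype=float),
        W1, b1, W2, b2, cfg.learning_rate, cfg.momentum, cfg.epochs,
    )
    return PerceptronModel(
        feature_names=tuple(data.X.columns), mean=mean, scale=scale,
        W1=W1, b1=b1, W2=W2, b2=b2, config=cfg,
    )


def _check_schema(feature_names: tuple[str, ...], X: pd.DataFrame) -> None:
    if tuple(X.columns) != tuple(feature_names):
        missing = [f for f in feature_names if f not in X.columns]
        extra = [c for c in X.columns if c not in feature_names]
        raise SchemaMismatchError(
            f"feature schema mismatch (missing={missing}, unexpected={extra})"
        )


def predict(model, X: pd.DataFrame) -> np.ndarray:
    """Boolean toxicant predictions from any trained model."""
    return model.predict(X)
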