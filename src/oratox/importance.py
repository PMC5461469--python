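"""Feature-importance protocols over balanced sub-datasets.

The dataset is partitioned into 100 equal-size subsets, each with (as far
as divisibility allows) the same toxicant/non-toxicant balance. Two
protocols score the features:

* **Ranker** -- per-subset information gain of each feature against the
  toxicant label (entropy in bits; continuous features are discretized by
  Fayyad-Irani MDL binning within the data being scored), summarized as
  mean and standard deviation across subsets;
* **WrapperEval** -- 100 hold-one-subset-out iterations of greedy forward
  feature selection with a decision-tree learner; a feature's importance
  is the number of iterations (0-100) in which it was selected. Candidate
  feature sets are scored on an internal stratified validation split of
  the 99 training subsets (the convention of wrapper subset evaluators,
  which score on the training data; the held-out subset's role is to vary
  the replicates).
  Scoring on the held-out subset itself (``mode="holdout"``) and a
  removal-impact variant (``mode="removal"``) are available as
  alternative readings of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .models import ModelingDataset

__all__ = ["make_balanced_subsets", "entropy_bits", "mdl_discretize",
           "information_gain", "ranker_evaluate", "wrapper_evaluate",
           "ImportanceReport"]


def make_balanced_subsets(
    labels: np.ndarray, n_subsets: int = 100, seed: int = 0
) -> list[np.ndarray]:
    """Partition instance indices into class-balanced subsets.

    Every instance lands in exactly one subset; subset sizes differ by at
    most one, as do per-subset class counts. Deterministic under ``seed``.
    """
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if min(n_pos, n_neg) < n_subsets:
        raise ValueError(
            f"need >= {n_subsets} members of each class "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    rng = np.random.default_rng(seed)
    pos = rng.permutation(np.flatnonzero(y))
    neg = rng.permutation(np.flatnonzero(~y))
    subsets: list[list[int]] = [[] for _ in range(n_subsets)]
    for offset, idx in enumerate(np.concatenate([pos, neg])):
        subsets[offset % n_subsets].append(int(idx))
    return [np.array(sorted(s), dtype=int) for s in subsets]


def entropy_bits(labels: np.ndarray) -> float:
    y = np.asarray(labels)
    if len(y) == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mdl_discretize(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Fayyad-Irani MDL cut points for a continuous feature.

    Recursively picks the boundary minimizing class-conditional entropy and
    keeps it only if the information gain beats the minimum-description-
    length cost; returns the sorted cut points (possibly empty).
    """
    order = np.argsort(x, kind="stable")
    xs = np.asarray(x, dtype=float)[order]
    ys = np.asarray(y, dtype=int)[order]
    cuts: list[float] = []
    _mdl_split(xs, ys, cuts)
    return sorted(cuts)


def _mdl_split(xs: np.ndarray, ys: np.ndarray, cuts: list[float]) -> None:
    n = len(ys)
    if n < 2:
        return
    base_ent = entropy_bits(ys)
    if base_ent == 0.0:
        return
    # candidate boundaries: midpoints where the value changes
    change = np.flatnonzero(np.diff(xs) > 0) + 1
    if change.size == 0:
        return
    best_gain, best_i, best_e1, best_e2 = -1.0, -1, 0.0, 0.0
    for i in change:
        e1 = entropy_bits(ys[:i])
        e2 = entropy_bits(ys[i:])
        gain = base_ent - (i / n) * e1 - ((n - i) / n) * e2
        if gain > best_gain:
            best_gain, best_i, best_e1, best_e2 = gain, int(i), e1, e2
    k = len(np.unique(ys))
    k1 = len(np.unique(ys[:best_i]))
    k2 = len(np.unique(ys[best_i:]))
    delta = np.log2(3.0**k - 2.0) - (
        k * base_ent - k1 * best_e1 - k2 * best_e2
    )
    threshold = (np.log2(n - 1.0) + delta) / n
    if best_gain <= threshold:
        return
    cuts.append(float((xs[best_i - 1] + xs[best_i]) / 2.0))
    _mdl_split(xs[:best_i], ys[:best_i], cuts)
    _mdl_split(xs[best_i:], ys[best_i:], cuts)


def _discretize_column(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Integer bin codes; binary/categorical-ish columns pass through."""
    values = np.unique(x)
    if values.size <= 4:
        return np.searchsorted(values, x)
    cuts = mdl_discretize(x, y)
    return np.searchsorted(np.asarray(cuts), x, side="right")


def information_gain(
    feature: np.ndarray, labels: np.ndarray, *, discretize: bool = True
) -> float:
    """H(labels) - H(labels | feature), in bits (non-negative).

    Continuous features are MDL-discretized against the labels first; a
    feature the discretizer refuses to split carries zero gain. Constant
    labels yield 0 by convention.
    """
    y = np.asarray(labels)
    x = np.asarray(feature, dtype=float)
    if len(x) != len(y):
        raise ValueError("feature and labels must align")
    base = entropy_bits(y)
    if base == 0.0:
        return 0.0
    codes = _discretize_column(x, y) if discretize else x.astype(int)
    cond = 0.0
    for code in np.unique(codes):
        mask = codes == code
        cond += mask.mean() * entropy_bits(y[mask])
    return max(0.0, base - cond)


@dataclass
class ImportanceReport:
    """Per-feature Ranker and/or WrapperEval scores.

    ``table`` is indexed by feature name with any of the columns
    ``ranker_mean``, ``ranker_std``, ``wrapper_count``; ``n_subsets`` and
    ``seed`` record the subset protocol.
    """

    table: pd.DataFrame
    n_subsets: int
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def ranker_evaluate(
    data: ModelingDataset,
    subsets: Sequence[np.ndarray],
    *,
    seed: int = 0,
) -> ImportanceReport:
    """Mean and std of per-subset information gain for every feature."""
    features = list(data.X.columns)
    gains = np.zeros((len(subsets), len(features)))
    for si, idx in enumerate(subsets):
        y = data.y[idx]
        for fi, name in enumerate(features):
            gains[si, fi] = information_gain(
                data.X[name].to_numpy(float)[idx], y
            )
    table = pd.DataFrame(
        {"ranker_mean": gains.mean(axis=0), "ranker_std": gains.std(axis=0)},
        index=pd.Index(features, name="feature"),
    ).sort_values("ranker_mean", ascending=False)
    return ImportanceReport(table=table, n_subsets=len(subsets), seed=seed)


def _tree_accuracy(X_tr, y_tr, X_te, y_te, cols, seed, max_depth):
    """(held-out accuracy, training accuracy) of a tree on the columns."""
    tree = DecisionTreeClassifier(
        criterion="entropy", max_depth=max_depth, random_state=seed
    )
    tree.fit(X_tr[:, cols], y_tr)
    test_acc = float((tree.predict(X_te[:, cols]) == y_te).mean())
    train_acc = float((tree.predict(X_tr[:, cols]) == y_tr).mean())
    return test_acc, train_acc


def _validation_split(y_tr, seed):
    """Stratified 75/25 split of the training subsets, for subset scoring."""
    skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=seed)
    tr, va = next(skf.split(np.zeros(len(y_tr)), y_tr))
    return tr, va


def wrapper_evaluate(
    data: ModelingDataset,
    subsets: Sequence[np.ndarray],
    *,
    mode: str = "forward",
    max_depth: int = 3,
    max_features: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Hold-one-subset-out wrapper selection with a decision-tree learner.

    ``mode="forward"``: greedy forward selection (at most ``max_features``
    features) scored on an internal stratified validation split of the
    training subsets; score = number of iterations in which the feature
    is selected. ``mode="holdout"``: the same search scored on the
    held-out subset. ``mode="removal"``: train on all features, remove
    one at a time; score = number of iterations in which removal reduced
    held-out accuracy.
    """
    if mode not in ("forward", "holdout", "removal"):
        raise ValueError(f"unknown wrapper mode {mode!r}")
    features = list(data.X.columns)
    X = data.X.to_numpy(float)
    y = data.y.astype(int)
    counts = np.zeros(len(features), dtype=int)
    for hold, test_idx in enumerate(subsets):
        train_idx = np.concatenate(
            [s for i, s in enumerate(subsets) if i != hold]
        )
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        if mode in ("forward", "holdout"):
            if mode == "forward":
                tr, va = _validation_split(y_tr, seed)
                score = lambda cols: _tree_accuracy(
                    X_tr[tr], y_tr[tr], X_tr[va], y_tr[va], cols, seed,
                    max_depth)
            else:
                score = lambda cols: _tree_accuracy(
                    X_tr, y_tr, X_te, y_te, cols, seed, max_depth)
            selected: list[int] = []
            remaining = list(range(len(features)))
            best_acc = -np.inf
            while remaining and len(selected) < max_features:
                # ties break by training accuracy, then lowest index
                scores = [score(selected + [f]) for f in remaining]
                top = max(range(len(scores)),
                          key=lambda i: (scores[i][0], scores[i][1], -i))
                if scores[top][0] <= best_acc:
                    break
                best_acc = scores[top][0]
                selected.append(remaining.pop(top))
            counts[selected] += 1
        else:
            full, _ = _tree_accuracy(X_tr, y_tr, X_te, y_te,
                                     list(range(len(features))), seed,
                                     max_depth)
            for fi in range(len(features)):
                cols = [c for c in range(len(features)) if c != fi]
                if _tree_accuracy(X_tr, y_tr, X_te, y_te, cols,
                                  seed, max_depth)[0] < full:
                    counts[fi] += 1
    table = pd.DataFrame(
        {"wrapper_count": counts},
        index=pd.Index(features, name="feature"),
    ).sort_values("wrapper_count", ascending=False)
    return ImportanceReport(table=table, n_subsets=len(subsets), seed=seed)
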