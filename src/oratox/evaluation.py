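"""Evaluation protocols: confusion summaries, per-module metrics,
stratified k-fold cross-validation with reweighting, and leave-one-out.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), balanced accuracy
(BAC) = their mean. A module with no positives has undefined sensitivity;
by report convention its BAC falls back to the specificity (the
``undefined_sensitivity`` flag is retained). Cross-validation pools the
held-out confusion counts (micro); per-fold macro averages are also kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .knn import KnnConfig, knn_feature_column, knn_predict_batch
from .models import ModelingDataset, compute_class_weights

__all__ = ["ConfusionSummary", "confusion", "per_module_confusion",
           "FoldResult", "stratified_kfold", "leave_one_out"]

Trainer = Callable[[ModelingDataset, int], object]


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    scope: str = "global"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        """Percent, or None when the module has no observed positives."""
        if self.tp + self.fn == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        if self.tn + self.fp == 0:
            return None
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def undefined_sensitivity(self) -> bool:
        return self.sensitivity is None

    @property
    def bac(self) -> float | None:
        """(sensitivity + specificity)/2; falls back to the defined rate."""
        rates = [r for r in (self.sensitivity, self.specificity) if r is not None]
        if not rates:
            return None
        return sum(rates) / len(rates)

    def as_row(self) -> dict:
        fmt = lambda v: float("nan") if v is None else round(v, 2)
        return {
            "scope": self.scope,
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
            "bac": fmt(self.bac),
            "fn": self.fn, "tp": self.tp, "tn": self.tn, "fp": self.fp,
            "total": self.n,
        }


def confusion(
    labels: np.ndarray, predictions: np.ndarray, scope: str = "global"
) -> ConfusionSummary:
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionSummary(
        tp=int((p & y).sum()),
        fp=int((p & ~y).sum()),
        fn=int((~p & y).sum()),
        tn=int((~p & ~y).sum()),
        scope=scope,
    )


def per_module_confusion(
    labels: np.ndarray,
    predictions: np.ndarray,
    modules: Sequence[int | None] | Mapping[str, int],
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Module-scoped confusion rows plus an ALL row (column-wise sum).

    Substances without a module id are excluded, mirroring the restriction
    of module metrics to graph-resident substances.
    """
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if isinstance(modules, Mapping):
        if ids is None:
            raise ValueError("ids required when modules is a mapping")
        modules = [modules.get(sid) for sid in ids]
    mods = np.array([-1 if m is None else int(m) for m in modules])
    rows = []
    for m in sorted(set(mods[mods >= 0])):
        mask = mods == m
        rows.append(confusion(y[mask], p[mask], scope=f"module:{m}").as_row())
    mask = mods >= 0
    rows.append(confusion(y[mask], p[mask], scope="ALL").as_row())
    return pd.DataFrame(rows).set_index("scope")


@dataclass
class FoldResult:
    pooled: ConfusionSummary
    per_fold: list[ConfusionSummary]
    predictions: np.ndarray  # aligned with the input dataset

    @property
    def macro_bac(self) -> float:
        rates = [f.bac for f in self.per_fold if f.bac is not None]
        return float(np.mean(rates))


def _fold_knn_features(
    data: ModelingDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    knn_cfg: KnnConfig,
) -> tuple[pd.Series, pd.Series]:
    """Recompute the KNN column against the training fold only."""
    fp = data.fingerprints
    ids = data.ids
    train_ids = [ids[i] for i in train_idx]
    col_train = knn_feature_column(
        fp[train_idx], train_ids, data.y[train_idx], knn_cfg
    )["knn"].to_numpy()
    preds = knn_predict_batch(
        fp[test_idx], [ids[i] for i in test_idx],
        fp[train_idx], train_ids, data.y[train_idx], knn_cfg,
    )
    col_test = np.array([int(p.prediction) for p in preds])
    return col_train, col_test


def stratified_kfold(
    data: ModelingDataset,
    trainer: Trainer,
    *,
    k: int = 10,
    seed: int = 0,
    reweight: bool = True,
    weight_mode: str = "paper",
    knn_cfg: KnnConfig | None = None,
    knn_mode: str = "fold",
) -> FoldResult:
    """Stratified k-fold CV with in-fold reweighting.

    Folds preserve class proportions to within one instance; every
    instance is held out exactly once and the held-out confusions are
    pooled. When the dataset carries fingerprints, a ``KNN`` feature
    column is recomputed inside each training fold (``knn_mode="fold"``,
    no label leakage) or taken as-is from the dataset
    (``knn_mode="global"``, the replicate-paper reading).
    """
    n_pos = int(data.y.sum())
    n_neg = data.n - n_pos
    if min(n_pos, n_neg) < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    if knn_mode not in ("fold", "global"):
        raise ValueError(f"unknown knn_mode {knn_mode!r}")
    recompute_knn = (
        knn_mode == "fold" and knn_cfg is not None
        and data.fingerprints is not None and "KNN" in data.X.columns
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.zeros(data.n, dtype=bool)
    per_fold: list[ConfusionSummary] = []
    for fold_i, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(data.n), data.y.astype(int))
    ):
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        if recompute_knn:
            col_train, col_test = _fold_knn_features(
                data, train_idx, test_idx, knn_cfg
            )
            train.X = train.X.assign(KNN=col_train)[list(data.X.columns)]
            test.X = test.X.assign(KNN=col_test)[list(data.X.columns)]
        if reweight:
            train.weights = compute_class_weights(train.y, weight_mode).weights
        model = trainer(train, seed + fold_i)
        fold_pred = model.predict(test.X)
        preds[test_idx] = fold_pred
        per_fold.append(confusion(test.y, fold_pred, scope=f"fold:{fold_i}"))
    pooled = confusion(data.y, preds, scope="pooled")
    return FoldResult(pooled=pooled, per_fold=per_fold, predictions=preds)


def leave_one_out(
    data: ModelingDataset,
    trainer: Trainer,
    *,
    seed: int = 0,
    reweight: bool = True,
    weight_mode: str = "paper",
    knn_cfg: KnnConfig | None = None,
    knn_mode: str = "fold",
    size_warning: int = 500,
) -> np.ndarray:
    """Per-substance predictions from models trained on all others.

    Expensive (n model fits); a warning is emitted above ``size_warning``
    instances. Deterministic under ``seed``; predictions do not depend on
    evaluation order.
    """
    if data.n < 2:
        raise ValueError("leave-one-out needs at least 2 instances")
    if data.n > size_warning:
        warnings.warn(
            f"leave-one-out on {data.n} instances trains {data.n} models",
            stacklevel=2,
        )
    recompute_knn = (
        knn_mode == "fold" and knn_cfg is not None
        and data.fingerprints is not None and "KNN" in data.X.columns
    )
    preds = np.zeros(data.n, dtype=bool)
    all_idx = np.arange(data.n)
    for i in range(data.n):
        train_idx = all_idx[all_idx != i]
        test_idx = np.array([i])
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        if recompute_knn:
            col_train, col_test = _fold_knn_features(
                data, train_idx, test_idx, knn_cfg
            )
            train.X = train.X.assign(KNN=col_train)[list(data.X.columns)]
            test.X = test.X.assign(KNN=col_test)[list(data.X.columns)]
        if reweight and 0 < train.y.sum() < train.n:
            train.weights = compute_class_weights(train.y, weight_mode).weights
        model = trainer(train, seed)
        preds[i] = bool(model.predict(test.X)[0])
    return preds
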