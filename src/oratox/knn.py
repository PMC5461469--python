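"""Similarity-constrained k-nearest-neighbor toxicant classifier.

A query substance is predicted an oral toxicant (LD50 < 2,000 mg/kg b.w.)
when the majority of its k = 5 most similar reference substances -- among
those with Tanimoto similarity >= 0.7 -- are toxicants. Substances with no
qualifying neighbor are outside the applicability domain and default to
the non-toxicant majority class. The per-substance prediction doubles as a
binary feature for the fused supervised learners.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .similarity import tanimoto_matrix

__all__ = ["KnnConfig", "KnnPrediction", "knn_predict", "knn_predict_batch",
           "knn_feature_column", "write_predictions"]


@dataclass(frozen=True)
class KnnConfig:
    k: int = 5
    neighbor_threshold: float = 0.7
    tie_rule: str = "predict_negative"
    self_exclusion: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.neighbor_threshold <= 1.0:
            raise ValueError("neighbor_threshold must be in [0, 1]")
        if self.tie_rule not in ("predict_negative", "predict_positive"):
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")


@dataclass(frozen=True)
class KnnPrediction:
    prediction: bool
    n_neighbors_used: int
    in_domain: bool


def _vote(labels_sorted: np.ndarray, cfg: KnnConfig) -> KnnPrediction:
    used = labels_sorted[: cfg.k]
    n_used = len(used)
    if n_used == 0:
        return KnnPrediction(cfg.tie_rule == "predict_positive", 0, False)
    pos = int(used.sum())
    neg = n_used - pos
    if pos > neg:
        pred = True
    elif pos < neg:
        pred = False
    else:
        pred = cfg.tie_rule == "predict_positive"
    return KnnPrediction(pred, n_used, True)


def _rank_candidates(
    sims: np.ndarray, ids: Sequence[str], mask: np.ndarray, cfg: KnnConfig
) -> np.ndarray:
    """Indices of qualifying candidates, most similar first.

    Ties at equal similarity (including at the k-th rank) break by
    ascending substance id for determinism.
    """
    cand = np.flatnonzero(mask & ~np.isnan(sims)
                          & (sims >= cfg.neighbor_threshold))
    order = sorted(cand, key=lambda i: (-sims[i], ids[i]))
    return np.asarray(order, dtype=int)


def knn_predict(
    query_fp: np.ndarray,
    reference_fps: np.ndarray,
    reference_labels: np.ndarray,
    cfg: KnnConfig = KnnConfig(),
    *,
    reference_ids: Sequence[str] | None = None,
    query_id: str | None = None,
) -> KnnPrediction:
    """Predict one substance against a labeled reference set."""
    query_fp = np.asarray(query_fp, dtype=np.uint8)
    reference_fps = np.asarray(reference_fps, dtype=np.uint8)
    if reference_fps.shape[0] == 0:
        raise ValueError("reference set is empty")
    if reference_fps.shape[1] != query_fp.shape[0]:
        raise ValueError("fingerprint length mismatch between query and reference")
    labels = np.asarray(reference_labels, dtype=bool)
    ids = list(reference_ids) if reference_ids is not None else [
        f"{i:08d}" for i in range(len(labels))
    ]
    sims = tanimoto_matrix(np.vstack([query_fp[None, :], reference_fps]))[0, 1:]
    mask = np.ones(len(labels), dtype=bool)
    if cfg.self_exclusion and query_id is not None:
        mask &= np.array([sid != query_id for sid in ids])
    order = _rank_candidates(sims, ids, mask, cfg)
    return _vote(labels[order], cfg)


def knn_predict_batch(
    query_fps: np.ndarray,
    query_ids: Sequence[str],
    reference_fps: np.ndarray,
    reference_ids: Sequence[str],
    reference_labels: np.ndarray,
    cfg: KnnConfig = KnnConfig(),
) -> list[KnnPrediction]:
    """Vectorized similarity scan; self-matches excluded by substance id."""
    query_fps = np.asarray(query_fps, dtype=np.uint8)
    reference_fps = np.asarray(reference_fps, dtype=np.uint8)
    if query_fps.shape[1] != reference_fps.shape[1]:
        raise ValueError("fingerprint length mismatch")
    labels = np.asarray(reference_labels, dtype=bool)
    n_q = query_fps.shape[0]
    stacked = tanimoto_matrix(np.vstack([query_fps, reference_fps]))
    sims = stacked[:n_q, n_q:]
    out = []
    ref_ids = list(reference_ids)
    for qi, qid in enumerate(query_ids):
        mask = np.ones(len(labels), dtype=bool)
        if cfg.self_exclusion:
            mask &= np.array([sid != qid for sid in ref_ids])
        order = _rank_candidates(sims[qi], ref_ids, mask, cfg)
        out.append(_vote(labels[order], cfg))
    return out


def knn_feature_column(
    fingerprints: np.ndarray,
    substance_ids: Sequence[str],
    labels: np.ndarray,
    cfg: KnnConfig = KnnConfig(),
) -> pd.DataFrame:
    """Leave-self-out KNN prediction for every substance.

    Returns a frame indexed by substance_id with columns ``knn`` (0/1),
    ``n_neighbors`` and ``in_domain``; row order follows the input.
    """
    preds = knn_predict_batch(
        fingerprints, substance_ids, fingerprints, substance_ids, labels, cfg
    )
    return pd.DataFrame(
        {
            "knn": [int(p.prediction) for p in preds],
            "n_neighbors": [p.n_neighbors_used for p in preds],
            "in_domain": [p.in_domain for p in preds],
        },
        index=pd.Index(substance_ids, name="substance_id"),
    )


def write_predictions(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")
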