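"""Tanimoto similarity, thresholded graph construction and module detection.

Substances whose binary substructure fingerprints share at least a 0.7
Tanimoto similarity are connected; greedy multi-level (Louvain-style)
modularity maximization on the resulting unweighted graph yields the
structural modules used as applicability domains downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .dossier import SubstanceRecord

__all__ = [
    "UndefinedSimilarityError",
    "SimilarityGraph",
    "tanimoto",
    "tanimoto_matrix",
    "build_graph",
    "detect_modules",
    "modularity_q",
    "write_edge_list",
    "write_module_table",
]


class UndefinedSimilarityError(ValueError):
    """Tanimoto similarity of two all-zero fingerprints is undefined."""


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| over equal-length bit vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise UndefinedSimilarityError("both fingerprints are empty")
    return float(np.count_nonzero(a & b)) / union


def tanimoto_matrix(fingerprints: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix; entries with an empty union are NaN."""
    F = np.asarray(fingerprints, dtype=np.int64)
    inter = F @ F.T
    pop = F.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return sim


@dataclass
class SimilarityGraph:
    """Thresholded Tanimoto graph with optional module assignments.

    Every stored edge has similarity >= ``threshold``; module ids, once
    assigned, are contiguous integers from 0 (largest module first).
    """

    graph: nx.Graph
    threshold: float
    module_of: dict[str, int] | None = None
    q: float | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_modules(self) -> int:
        if self.module_of is None:
            raise ValueError("modules not yet detected")
        return len(set(self.module_of.values()))


def build_graph(
    substances: Sequence[SubstanceRecord] | tuple[Sequence[str], np.ndarray],
    threshold: float = 0.7,
) -> SimilarityGraph:
    """Connect substance pairs whose Tanimoto similarity >= ``threshold``.

    Accepts either SubstanceRecords or an ``(ids, fingerprint_matrix)``
    pair. Pairs whose similarity is undefined (both empty) are skipped.
    """
    if isinstance(substances, tuple):
        ids, F = substances
        ids = list(ids)
        F = np.asarray(F, dtype=np.uint8)
    else:
        ids = [s.substance_id for s in substances]
        F = np.asarray([s.fingerprint for s in substances], dtype=np.uint8)
    if len(ids) < 2:
        raise ValueError("need at least 2 substances")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate substance ids")

    sim = tanimoto_matrix(F)
    g = nx.Graph()
    g.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = ~np.isnan(sim[iu, ju]) & (sim[iu, ju] >= threshold)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], similarity=float(sim[i, j]))
    return SimilarityGraph(graph=g, threshold=threshold)


def modularity_q(
    graph: SimilarityGraph | nx.Graph, partition: Mapping[str, int]
) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2], unweighted.

    ``partition`` maps every node to a module id; a missing node is a
    usage error. An edgeless graph has Q = 0 by convention.
    """
    g = graph.graph if isinstance(graph, SimilarityGraph) else graph
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition misses {len(missing)} nodes, e.g. {missing[0]!r}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict[int, int] = {}
    degree: dict[int, int] = {}
    for u, v in g.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    for node, deg in g.degree:
        degree[partition[node]] = degree.get(partition[node], 0) + deg
    q = 0.0
    for c, d_c in degree.items():
        q += intra.get(c, 0) / m - (d_c / (2.0 * m)) ** 2
    return q


def _canonical_module_ids(communities: Iterable[set]) -> dict[str, int]:
    """Relabel communities as contiguous ids: largest first, ties by min node."""
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {node: i for i, comm in enumerate(ordered) for node in comm}


def detect_modules(
    graph: SimilarityGraph, *, seed: int = 0, n_restarts: int = 8
) -> SimilarityGraph:
    """Greedy multi-level modularity maximization (resolution 1, unweighted).

    Runs the Louvain heuristic ``n_restarts`` times with seeded node
    orders and keeps the partition with the highest Q (scored by
    :func:`modularity_q`, so the selection is independent of the search).
    Isolated nodes become singleton modules. An edgeless graph yields the
    all-singleton partition with Q = 0 and a warning.
    """
    g = graph.graph
    if g.number_of_edges() == 0:
        warnings.warn("edgeless graph: all-singleton partition, Q = 0",
                      stacklevel=2)
        graph.module_of = {n: i for i, n in enumerate(sorted(g.nodes))}
        graph.q = 0.0
        return graph
    best_partition = None
    best_q = -np.inf
    for r in range(max(1, n_restarts)):
        communities = nx.community.louvain_communities(
            g, weight=None, resolution=1.0, seed=seed + r
        )
        partition = {n: i for i, comm in enumerate(communities) for n in comm}
        q = modularity_q(graph, partition)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = communities
    graph.module_of = _canonical_module_ids(best_partition)
    graph.q = best_q
    return graph


def write_edge_list(graph: SimilarityGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tsimilarity\n")
        for u, v, data in sorted(graph.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['similarity']:.6f}\n")


def write_module_table(graph: SimilarityGraph, path: str | Path) -> None:
    if graph.module_of is None:
        raise ValueError("modules not yet detected")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("substance_id\tmodule\n")
        for node in sorted(graph.module_of):
            fh.write(f"{node}\t{graph.module_of[node]}\n")
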