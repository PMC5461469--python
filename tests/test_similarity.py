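"""Tanimoto similarity, graph thresholding and modularity maximization."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from oratox.similarity import (
    SimilarityGraph,
    UndefinedSimilarityError,
    build_graph,
    detect_modules,
    modularity_q,
    tanimoto,
    tanimoto_matrix,
)
from oratox.synthetic import GeneratorConfig, generate_fingerprints


def bits(on, length=16):
    v = np.zeros(length, dtype=np.uint8)
    v[list(on)] = 1
    return v


class TestTanimoto:
    def test_identical_is_one(self):
        assert tanimoto(bits({1, 5}), bits({1, 5})) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(bits({1, 2}), bits({3, 4})) == 0.0

    def test_partial_overlap(self):
        # |{2,3}| / |{1,2,3,4}| = 0.5 by enumeration
        assert tanimoto(bits({1, 2, 3}), bits({2, 3, 4})) == 0.5

    def test_both_empty_is_error(self):
        with pytest.raises(UndefinedSimilarityError):
            tanimoto(bits(set()), bits(set()))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 15)),
        b=st.sets(st.integers(0, 15)),
    )
    def test_symmetric_and_one_iff_equal(self, a, b):
        if not (a | b):
            return
        s_ab = tanimoto(bits(a), bits(b))
        assert s_ab == tanimoto(bits(b), bits(a))
        assert 0.0 <= s_ab <= 1.0
        assert (s_ab == 1.0) == (a == b)


class TestBuildGraph:
    def test_threshold_zero_complete(self):
        rng = np.random.default_rng(0)
        F = (rng.random((6, 32)) < 0.5).astype(np.uint8)
        F[F.sum(axis=1) == 0, 0] = 1
        g = build_graph(([f"S{i}" for i in range(6)], F), threshold=0.0)
        assert g.graph.number_of_edges() == 15

    def test_threshold_above_one_empty(self):
        F = np.ones((3, 8), dtype=np.uint8)
        g = build_graph((["a", "b", "c"], F), threshold=1.01)
        assert g.graph.number_of_edges() == 0

    def test_duplicate_ids_rejected(self):
        F = np.ones((2, 8), dtype=np.uint8)
        with pytest.raises(ValueError, match="duplicate"):
            build_graph((["a", "a"], F))

    def test_edges_match_brute_force_scan(self):
        cfg = GeneratorConfig(seed=5, n_substances=60, n_modules=2,
                              within_module_similarity=0.9)
        subs = generate_fingerprints(cfg)
        ids = [s.substance_id for s in subs]
        F = np.array([s.fingerprint for s in subs])
        g = build_graph((ids, F), threshold=0.7)
        expected = set()
        for i, j in itertools.combinations(range(len(ids)), 2):
            if tanimoto(F[i], F[j]) >= 0.7:
                expected.add(frozenset({ids[i], ids[j]}))
        got = {frozenset(e) for e in g.graph.edges}
        assert got == expected
        # strong two-module separation: no between-module edges at 0.7
        modules = cfg.module_assignment()
        for u, v in g.graph.edges:
            assert modules[ids.index(u)] == modules[ids.index(v)]


def _all_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _brute_force_optimum(g: nx.Graph) -> float:
    best = -1.0
    for part in _all_partitions(list(g.nodes)):
        mapping = {n: i for i, c in enumerate(part) for n in c}
        best = max(best, modularity_q(g, mapping))
    return best


class TestModularity:
    def test_single_module_is_zero(self):
        g = nx.complete_graph(5)
        assert modularity_q(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_two_disjoint_cliques_half(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = {n: int(n >= 4) for n in g.nodes}
        assert modularity_q(g, part) == pytest.approx(0.5)

    def test_missing_node_is_usage_error(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="misses"):
            modularity_q(g, {0: 0, 1: 0})

    def test_q_within_known_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = nx.gnp_random_graph(7, 0.5, seed=int(rng.integers(1 << 20)))
            if g.number_of_edges() == 0:
                continue
            part = {n: int(rng.integers(3)) for n in g.nodes}
            assert -0.5 <= modularity_q(g, part) < 1.0


class TestDetectModules:
    def test_two_triangles_with_bridge(self):
        g = nx.Graph(
            [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        )
        sg = SimilarityGraph(graph=g, threshold=0.7)
        detect_modules(sg, seed=0)
        triangles = {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        found = {}
        for n, m in sg.module_of.items():
            found.setdefault(m, set()).add(n)
        assert {frozenset(c) for c in found.values()} == triangles
        assert sg.q == pytest.approx(_brute_force_optimum(g))

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        sg = SimilarityGraph(graph=g, threshold=0.7)
        detect_modules(sg, seed=0)
        assert sg.n_modules == 1
        assert sg.q == pytest.approx(0.0)

    def test_edgeless_graph_singletons_with_warning(self):
        g = nx.empty_graph(4)
        sg = SimilarityGraph(graph=g, threshold=0.7)
        with pytest.warns(UserWarning, match="edgeless"):
            detect_modules(sg, seed=0)
        assert sg.n_modules == 4
        assert sg.q == 0.0

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        # corpus of 50 random graphs with at most 8 nodes
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 9))
            p = float(rng.uniform(0.25, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            sg = SimilarityGraph(graph=g, threshold=0.7)
            detect_modules(sg, seed=0)
            optimum = _brute_force_optimum(g)
            assert sg.q <= optimum + 1e-9
            assert sg.q == pytest.approx(optimum, abs=1e-9)
            checked += 1

    def test_beats_trivial_partitions(self):
        g = nx.karate_club_graph()
        sg = SimilarityGraph(graph=g, threshold=0.7)
        detect_modules(sg, seed=0)
        singletons = {n: i for i, n in enumerate(g.nodes)}
        one_module = {n: 0 for n in g.nodes}
        assert sg.q >= modularity_q(g, singletons)
        assert sg.q >= modularity_q(g, one_module)

    def test_recovers_nine_planted_modules(self):
        cfg = GeneratorConfig(seed=3, n_substances=270, n_modules=9,
                              within_module_similarity=0.95)
        subs = generate_fingerprints(cfg)
        ids = [s.substance_id for s in subs]
        F = np.array([s.fingerprint for s in subs])
        sg = detect_modules(build_graph((ids, F), 0.7), seed=0)
        assert sg.n_modules == 9
        truth = cfg.module_assignment()
        found = [sg.module_of[i] for i in ids]
        assert adjusted_rand_score(truth, found) > 0.9

    def test_module_ids_contiguous_from_zero(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
        g.add_node(99)  # isolated node becomes a singleton module
        sg = SimilarityGraph(graph=g, threshold=0.7)
        detect_modules(sg, seed=0)
        assert sorted(set(sg.module_of.values())) == list(range(sg.n_modules))
        assert sg.module_of[99] is not None
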