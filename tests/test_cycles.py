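"""Cycle algebra: counting, enumeration, canonical dedup, ranking."""

import itertools

import networkx as nx
import numpy as np
import pytest

from kepsolve import (
    CompatibilityGraph,
    Cycle,
    ValidationError,
    canonicalize,
    count_cycles,
    evaluate_cycles,
    find_cycles,
    unweighted_adjacency,
)


def random_graph(rng, n, density=0.4, max_w=9):
    w = (rng.random((n, n)) < density) * rng.integers(1, max_w + 1, size=(n, n))
    np.fill_diagonal(w, 0)
    return CompatibilityGraph(weights=w.astype(np.int64))


def graph(mat):
    return CompatibilityGraph(weights=np.array(mat, dtype=np.int64))


TRIANGLE = graph([[0, 1, 0], [0, 0, 2], [3, 0, 0]])
TWO_CYCLE = graph([[0, 1], [1, 0]])


class TestAdjacency:
    def test_thresholding(self):
        assert unweighted_adjacency(graph([[0, 5], [2, 0]])).tolist() == [[0, 1], [1, 0]]
        assert not unweighted_adjacency(graph([[0, 0], [0, 0]])).any()

    def test_random_matches_elementwise(self, rng):
        g = random_graph(rng, 8)
        assert (unweighted_adjacency(g) == (g.weights > 0)).all()


class TestCounting:
    @pytest.mark.parametrize("g, L, expected",
                             [(TWO_CYCLE, 2, 2), (TRIANGLE, 3, 3), (TRIANGLE, 2, 0),
                              (graph([[0, 0], [0, 0]]), 2, 0)])
    def test_examples(self, g, L, expected):
        assert count_cycles(g, L) == expected

    @pytest.mark.parametrize("L", [2, 3])
    def test_trace_equals_brute_force_walk_count(self, rng, L):
        """trace(A^L) counts the closed length-L walks over all n^L vertex
        sequences (brute-force oracle at small n)."""
        for _ in range(10):
            g = random_graph(rng, 5)
            a = unweighted_adjacency(g)
            walks = sum(
                all(a[seq[i], seq[(i + 1) % L]] for i in range(L))
                for seq in itertools.product(range(5), repeat=L)
            )
            assert count_cycles(g, L) == walks

    def test_length_bounds(self):
        with pytest.raises(ValidationError):
            count_cycles(TRIANGLE, 4)
        assert count_cycles(TRIANGLE, 4, max_length=5) == 0


class TestEnumeration:
    def test_triangle_rotations_and_weights(self):
        cl = find_cycles(TRIANGLE, 3)
        assert cl.n_raw == 3
        assert all(c.weight == 6 for c in cl.cycles)
        starts = sorted(c.vertices[0] for c in cl.cycles)
        assert starts == [0, 1, 2]

    def test_two_cycle(self):
        cl = find_cycles(TWO_CYCLE, 2)
        assert sorted(c.vertices for c in cl.cycles) == [(0, 1), (1, 0)]
        assert all(c.weight == 2 for c in cl.cycles)

    def test_no_cycles(self):
        assert find_cycles(graph([[0, 1], [0, 0]]), 2).cycles == ()


class TestCanonical:
    @pytest.mark.parametrize("vertices, expected",
                             [((2, 0, 1), (0, 1, 2)), ((0, 1, 2), (0, 1, 2)),
                              ((5, 3), (3, 5)), ((1, 2, 0), (0, 1, 2))])
    def test_rotation(self, vertices, expected):
        assert canonicalize(Cycle(vertices=vertices, weight=1)).vertices == expected

    def test_direction_preserved(self):
        # (2, 1, 0) walks 2->1->0->2; rotating to 0 first keeps that order
        assert canonicalize(Cycle(vertices=(2, 1, 0), weight=1)).vertices == (0, 2, 1)


class TestEvaluate:
    def test_dedup_triangle(self):
        cl = evaluate_cycles(TRIANGLE, 3, k=10)
        assert [c.vertices for c in cl.cycles] == [(0, 1, 2)]
        assert cl.cycles[0].weight == 6
        assert cl.n_unique == 1

    def test_topk_truncation(self):
        g = graph([
            [0, 2, 0, 0],
            [2, 0, 0, 0],
            [0, 0, 0, 4],
            [0, 0, 3, 0],
        ])
        cl = evaluate_cycles(g, 2, k=1)
        assert [c.vertices for c in cl.cycles] == [(2, 3)]
        assert cl.cycles[0].weight == 7

    def test_tie_break_lexicographic(self):
        g = graph([
            [0, 1, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 0, 1],
            [0, 0, 1, 0],
        ])
        cl = evaluate_cycles(g, 2)
        assert [c.vertices for c in cl.cycles] == [(0, 1), (2, 3)]


@pytest.mark.parametrize("L", [2, 3])
def test_cycle_algebra_identities_random(rng, L):
    """On random digraphs: raw count == trace == L * unique, the floor
    identity holds, and the canonical set matches an independent DFS
    enumerator (networkx simple_cycles bounded by L)."""
    for _ in range(25):
        n = int(rng.integers(2, 13))
        g = random_graph(rng, n, density=float(rng.uniform(0.1, 0.6)))
        raw = find_cycles(g, L)
        unique = evaluate_cycles(g, L)
        trace = count_cycles(g, L)
        assert raw.n_raw == trace
        assert len(raw.cycles) == trace
        assert trace == L * len(unique.cycles)
        assert unique.n_unique == raw.n_raw // L

        dg = nx.from_numpy_array(g.weights, create_using=nx.DiGraph)
        oracle = {
            tuple(c) for c in nx.simple_cycles(dg, length_bound=L) if len(c) == L
        }
        mine = set()
        for c in unique.cycles:
            i = c.vertices.index(min(c.vertices))
            mine.add(c.vertices[i:] + c.vertices[:i])
        oracle_canon = set()
        for c in oracle:
            i = c.index(min(c))
            oracle_canon.add(c[i:] + c[:i])
        assert mine == oracle_canon


def test_relabeling_invariance(rng):
    """Permuting vertex labels permutes the unique cycle set accordingly."""
    g = random_graph(rng, 6)
    perm = np.array([4, 2, 0, 5, 1, 3])
    pw = np.zeros_like(g.weights)
    for i in range(6):
        for j in range(6):
            pw[perm[i], perm[j]] = g.weights[i, j]
    g2 = CompatibilityGraph(weights=pw)
    orig = {
        frozenset(c.vertices): c.weight for c in evaluate_cycles(g, 2).cycles
    }
    relab = {
        frozenset(int(perm[v]) for v in key): wt for key, wt in orig.items()
    }
    new = {
        frozenset(c.vertices): c.weight for c in evaluate_cycles(g2, 2).cycles
    }
    assert new == relab
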