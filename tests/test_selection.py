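"""Greedy disjoint cycle packing vs the exhaustive oracle."""

import numpy as np
import pytest

from kepsolve import Cycle, ValidationError, brute_force_optimum, disjoint, select_solution
from kepsolve.cycles import CycleList


def cl(*specs):
    """CycleList from (vertices, weight) tuples, pre-sorted as evaluate_cycles
    produces them: weight descending, then lexicographic."""
    cycles = tuple(
        Cycle(vertices=v, weight=w)
        for v, w in sorted(specs, key=lambda s: (-s[1], s[0]))
    )
    return CycleList(cycles=cycles, n_raw=2 * len(cycles), n_unique=len(cycles))


class TestDisjoint:
    def test_examples(self):
        a, b, c = Cycle((0, 1), 1), Cycle((2, 3), 1), Cycle((1, 2), 1)
        assert disjoint(a, b)
        assert not disjoint(a, c)
        assert not disjoint(a, a)


class TestGreedy:
    def test_single_cycle(self):
        sol = select_solution(cl(((0, 1), 5)))
        assert sol.total_weight == 5
        assert [c.vertices for c in sol.cycles] == [(0, 1)]

    def test_multi_seed_escapes_heaviest_trap(self):
        """Heaviest cycle (1,2) w=6 blocks both others; the seed starting at
        (0,1) collects {(0,1),(2,3)} with total 9 and wins."""
        sol = select_solution(cl(((0, 1), 5), ((2, 3), 4), ((1, 2), 6)))
        assert sol.total_weight == 9
        assert sorted(c.vertices for c in sol.cycles) == [(0, 1), (2, 3)]

    def test_all_conflicting_takes_heaviest(self):
        sol = select_solution(cl(((0, 1), 3), ((1, 2), 7), ((0, 2), 5)))
        assert sol.total_weight == 7
        assert [c.vertices for c in sol.cycles] == [(1, 2)]

    def test_empty_input(self):
        sol = select_solution(CycleList(cycles=(), n_raw=0, n_unique=0))
        assert sol.total_weight == 0 and sol.cycles == ()

    def test_assignment_table(self):
        sol = select_solution(cl(((0, 1, 2), 6)))
        # donor of each pair serves the next pair's recipient
        assert sol.assignments() == {1: 0, 2: 1, 0: 2}


class TestBruteForce:
    def test_matches_spec_example(self):
        opt = brute_force_optimum(cl(((0, 1), 5), ((2, 3), 4), ((1, 2), 6)))
        assert opt.total_weight == 9

    def test_empty(self):
        assert brute_force_optimum(CycleList(cycles=(), n_raw=0, n_unique=0)).total_weight == 0

    def test_conflict_free_selects_all(self):
        opt = brute_force_optimum(cl(((0, 1), 2), ((2, 3), 3), ((4, 5), 4)))
        assert opt.total_weight == 9
        assert len(opt.cycles) == 3

    def test_size_guard(self):
        cycles = tuple(Cycle((2 * i, 2 * i + 1), 1) for i in range(21))
        with pytest.raises(ValidationError, match="reduce the instance"):
            brute_force_optimum(CycleList(cycles=cycles, n_raw=42, n_unique=21))


def random_instance(rng, n_vertices=10, n_cycles=8):
    specs = []
    seen = set()
    for _ in range(n_cycles):
        L = int(rng.integers(2, 4))
        vs = tuple(int(v) for v in rng.choice(n_vertices, size=L, replace=False))
        i = vs.index(min(vs))
        vs = vs[i:] + vs[:i]
        if vs in seen:
            continue
        seen.add(vs)
        specs.append((vs, int(rng.integers(1, 20))))
    return cl(*specs) if specs else CycleList(cycles=(), n_raw=0, n_unique=0)


def test_greedy_bounds_on_random_instances(rng):
    """greedy <= exhaustive optimum; greedy >= heaviest single cycle;
    equality with the optimum on conflict-free instances."""
    for _ in range(60):
        inst = random_instance(rng)
        greedy = select_solution(inst)
        opt = brute_force_optimum(inst)
        assert greedy.total_weight <= opt.total_weight
        if inst.cycles:
            assert greedy.total_weight >= max(c.weight for c in inst.cycles)
        conflict_free = all(
            disjoint(a, b)
            for i, a in enumerate(inst.cycles)
            for b in inst.cycles[i + 1:]
        )
        if conflict_free:
            assert greedy.total_weight == opt.total_weight


def test_greedy_maximality(rng):
    """No remaining cycle is disjoint from every selected cycle."""
    for _ in range(30):
        inst = random_instance(rng)
        sol = select_solution(inst)
        chosen = set(sol.cycles)
        used = {v for c in sol.cycles for v in c.vertices}
        for c in inst.cycles:
            if c not in chosen:
                assert used.intersection(c.vertices), (
                    "greedy left a compatible cycle unselected"
                )
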