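"""Final solution selection: vertex-disjoint cycle packing.

The exchange program executes a set of pairwise vertex-disjoint cycles
(each donor-recipient pair takes part in at most one exchange).  Selection
is greedy: every unique cycle seeds one candidate set, which is then
extended by scanning the remaining cycles in descending-weight order and
adding each cycle disjoint from all members; the candidate set with the
maximal total weight wins.  The greedy answer is locally optimal; an
exhaustive optimizer is provided as an oracle for small instances.

Ties between candidate sets are broken deterministically by (1) fewer
cycles, then (2) lexicographically greatest inclusion-bit sequence over the
ranked cycle list — i.e. the set containing the higher-priority cycle at
the first divergence wins.  The same rule is evaluated obliviously by the
secret-sharing backend, which keeps the two backends bit-for-bit equal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cycles import Cycle, CycleList
from .hla import ValidationError

__all__ = ["Solution", "disjoint", "select_solution", "brute_force_optimum"]

#: Guard for the exhaustive optimizer (2^n subsets).
BRUTE_FORCE_LIMIT = 20


@dataclass(frozen=True)
class Solution:
    """A vertex-disjoint set of exchange cycles and its total weight."""

    cycles: tuple[Cycle, ...]
    total_weight: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.cycles:
            if c.weight <= 0:
                raise ValidationError("solution cycles must have positive weight")
            overlap = seen.intersection(c.vertices)
            if overlap:
                raise ValidationError(
                    f"solution cycles are not vertex-disjoint (vertex {min(overlap)})"
                )
            seen.update(c.vertices)
        if self.total_weight != sum(c.weight for c in self.cycles):
            raise ValidationError("total_weight must equal the sum of member weights")

    def assignments(self) -> dict[int, int]:
        """Recipient pair id -> donor pair id, derived from the cycle edges."""
        out: dict[int, int] = {}
        for c in self.cycles:
            vs = c.vertices
            for i, donor_pair in enumerate(vs):
                out[vs[(i + 1) % len(vs)]] = donor_pair
        return out


def disjoint(c1: Cycle, c2: Cycle) -> bool:
    """True iff the two cycles share no vertex."""
    return not set(c1.vertices).intersection(c2.vertices)


def _greedy_bits(cycles: tuple[Cycle, ...], seed: int) -> tuple[int, ...]:
    """Inclusion bits of the candidate set seeded at index ``seed``.

    Scans the seed first, then the remaining cycles in ranked order, adding
    each cycle disjoint from all previously added ones.
    """
    m = len(cycles)
    order = [seed] + [j for j in range(m) if j != seed]
    bits = [0] * m
    used: set[int] = set()
    for j in order:
        c = cycles[j]
        if c.weight > 0 and not used.intersection(c.vertices):
            bits[j] = 1
            used.update(c.vertices)
    return tuple(bits)


def _solution_from_bits(cycles: tuple[Cycle, ...], bits) -> Solution:
    chosen = tuple(c for c, b in zip(cycles, bits) if b)
    return Solution(cycles=chosen, total_weight=sum(c.weight for c in chosen))


def select_solution(unique_cycles: CycleList, *, verbose: bool = False):
    """Greedy multi-seed vertex-disjoint cycle packing.

    ``unique_cycles`` must already be deduplicated and weight-sorted (the
    output of :func:`kepsolve.cycles.evaluate_cycles`).  One candidate set is
    built per seed cycle; the set with the highest total weight is returned
    (ties: fewer cycles, then lexicographically greatest inclusion bits).
    With ``verbose=True`` returns ``(best, all_candidates)``.
    """
    cycles = unique_cycles.cycles
    if not cycles:
        empty = Solution(cycles=(), total_weight=0)
        return (empty, [empty]) if verbose else empty

    candidates: list[tuple[int, tuple[int, ...]]] = []
    best_key: tuple | None = None
    best_bits: tuple[int, ...] | None = None
    for seed in range(len(cycles)):
        bits = _greedy_bits(cycles, seed)
        total = sum(c.weight for c, b in zip(cycles, bits) if b)
        candidates.append((total, bits))
        # higher total, then fewer cycles, then lex-greatest inclusion bits
        key = (total, -sum(bits), bits)
        if best_key is None or key > best_key:
            best_key, best_bits = key, bits

    best = _solution_from_bits(cycles, best_bits)
    if verbose:
        return best, [_solution_from_bits(cycles, b) for _, b in candidates]
    return best


def brute_force_optimum(unique_cycles: CycleList) -> Solution:
    """Exhaustive maximum-weight disjoint cycle packing (test/report oracle).

    Enumerates all disjoint subsets; only feasible for small instances
    (guarded at 20 unique cycles).
    """
    cycles = tuple(c for c in unique_cycles.cycles if c.weight > 0)
    m = len(cycles)
    if m > BRUTE_FORCE_LIMIT:
        raise ValidationError(
            f"{m} cycles exceed the exhaustive-search guard of "
            f"{BRUTE_FORCE_LIMIT}; reduce the instance"
        )
    vertex_sets = [frozenset(c.vertices) for c in cycles]
    best_bits: tuple[int, ...] = (0,) * m
    best_key = (0, 0, best_bits)

    def recurse(i: int, bits: list[int], used: frozenset, total: int) -> None:
        nonlocal best_bits, best_key
        if i == m:
            key = (total, -sum(bits), tuple(bits))
            if key > best_key:
                best_key, best_bits = key, tuple(bits)
            return
        recurse(i + 1, bits + [0], used, total)
        if not used & vertex_sets[i]:
            recurse(i + 1, bits + [1], used | vertex_sets[i], total + cycles[i].weight)

    recurse(0, [], frozenset(), 0)
    return _solution_from_bits(cycles, best_bits)
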