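"""Exchange-cycle counting, enumeration, deduplication and ranking.

The number of closed walks of a public length L in the compatibility
digraph is the trace of the L-th power of the unweighted adjacency matrix
(computed by naive repeated multiplication, as the share-domain backend
does).  Because the diagonal is zero, every closed walk of length 2 or 3
visits distinct vertices, so the trace counts exactly the simple exchange
cycles — each one L times, once per rotation start ("congruent"
duplicates).  Deduplication rotates each cycle so its minimum vertex comes
first; direction is preserved, as congruent duplicates differ only in the
start vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import CompatibilityGraph
from .hla import ValidationError

__all__ = [
    "Cycle",
    "CycleList",
    "DEFAULT_MAX_CYCLE_LENGTH",
    "unweighted_adjacency",
    "count_cycles",
    "find_cycles",
    "canonicalize",
    "evaluate_cycles",
]

#: Simultaneous-surgery logistics cap the practical exchange-cycle length.
DEFAULT_MAX_CYCLE_LENGTH = 3


@dataclass(frozen=True)
class Cycle:
    """An exchange cycle: ordered vertices plus aggregated edge weight."""

    vertices: tuple[int, ...]
    weight: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", tuple(int(v) for v in self.vertices))
        object.__setattr__(self, "weight", int(self.weight))
        if len(set(self.vertices)) != len(self.vertices):
            raise ValidationError(f"cycle vertices must be distinct: {self.vertices}")

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class CycleList:
    """A list of cycles plus the raw (duplicate-inclusive) count bookkeeping."""

    cycles: tuple[Cycle, ...]
    n_raw: int
    n_unique: int
    k: int | None = None


def _check_length(L: int, max_length: int) -> None:
    if not 2 <= L <= max_length:
        raise ValidationError(
            f"cycle length must be in 2..{max_length}, got {L}"
        )


def unweighted_adjacency(g: CompatibilityGraph) -> np.ndarray:
    """0/1 adjacency: entry 1 iff the weighted entry is > 0."""
    return (g.weights > 0).astype(np.int64)


def count_cycles(g: CompatibilityGraph, L: int,
                 max_length: int = DEFAULT_MAX_CYCLE_LENGTH) -> int:
    """Trace of the L-th adjacency-matrix power: closed walks of length L.

    Includes congruent duplicates (each simple cycle counted once per start
    vertex).  This count is the public, declassified output of the cycle-
    computation phase.
    """
    _check_length(L, max_length)
    a = unweighted_adjacency(g)
    power = a
    for _ in range(L - 1):  # naive repeated multiplication
        power = power @ a
    return int(np.trace(power))


def _walks(g: CompatibilityGraph, L: int):
    """All closed walks of length L over distinct vertices, every start vertex."""
    w = g.weights
    n = g.n

    def extend(path: tuple[int, ...], acc: int):
        if len(path) == L:
            closing = w[path[-1], path[0]]
            if closing > 0:
                yield path, acc + int(closing)
            return
        for v in range(n):
            if v in path:
                continue
            e = w[path[-1], v]
            if e > 0:
                yield from extend(path + (v,), acc + int(e))

    for start in range(n):
        yield from extend((start,), 0)


def find_cycles(g: CompatibilityGraph, L: int,
                max_length: int = DEFAULT_MAX_CYCLE_LENGTH) -> CycleList:
    """Enumerate all exchange cycles of length L, including duplicates.

    Each distinct cycle appears L times (once per rotation start); its weight
    is the sum of the traversed edge weights.  The number of entries equals
    ``count_cycles(g, L)`` for L in {2, 3}.
    """
    _check_length(L, max_length)
    cycles = tuple(Cycle(vertices=p, weight=wt) for p, wt in _walks(g, L))
    return CycleList(
        cycles=cycles, n_raw=len(cycles), n_unique=len(cycles) // L
    )


def canonicalize(c: Cycle) -> Cycle:
    """Rotate the vertex list so the minimum vertex index comes first.

    Rotation only — direction is preserved, since congruent duplicates differ
    by start vertex, not orientation.
    """
    i = c.vertices.index(min(c.vertices))
    return Cycle(vertices=c.vertices[i:] + c.vertices[:i], weight=c.weight)


def evaluate_cycles(g: CompatibilityGraph, L: int, k: int | None = None,
                    max_length: int = DEFAULT_MAX_CYCLE_LENGTH) -> CycleList:
    """Deduplicate, rank and truncate the exchange cycles of length L.

    Congruent duplicates are removed by canonical rotation; the unique cycles
    are sorted by weight descending (ties: lexicographically smaller canonical
    vertex list first) and truncated to the top ``k`` (default: all).
    """
    if k is not None and k < 1:
        raise ValidationError(f"top-k bound must be >= 1, got {k}")
    raw = find_cycles(g, L, max_length=max_length)
    unique: dict[tuple[int, ...], Cycle] = {}
    for c in raw.cycles:
        canon = canonicalize(c)
        unique.setdefault(canon.vertices, canon)
    ordered = sorted(unique.values(), key=lambda c: (-c.weight, c.vertices))
    if k is not None:
        ordered = ordered[:k]
    return CycleList(
        cycles=tuple(ordered),
        n_raw=raw.n_raw,
        n_unique=raw.n_raw // L,
        k=k,
    )
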