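"""Cleartext reference pipeline: the same four phases, no sharing.

Used directly for plain matching runs and as the ground truth the simulated
secret-sharing backend must reproduce bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cycles import DEFAULT_MAX_CYCLE_LENGTH, CycleList, evaluate_cycles, find_cycles
from .graph import CompatibilityGraph, compute_compatibility_graph
from .medical import Pair, WeightConfig
from .selection import Solution, select_solution

__all__ = ["PipelineResult", "run_pipeline_clear"]


@dataclass(frozen=True)
class PipelineResult:
    """All intermediate artefacts of a cleartext run."""

    graph: CompatibilityGraph
    raw_cycle_count: int
    unique_cycles: CycleList
    solution: Solution


def run_pipeline_clear(
    pairs: list[Pair],
    cfg: WeightConfig | None = None,
    L: int = 2,
    k: int | None = None,
    max_length: int = DEFAULT_MAX_CYCLE_LENGTH,
) -> PipelineResult:
    """Match, enumerate, rank and pack exchange cycles in the clear."""
    cfg = cfg or WeightConfig()
    graph = compute_compatibility_graph(pairs, cfg)
    raw = find_cycles(graph, L, max_length=max_length)
    unique = evaluate_cycles(graph, L, k=k, max_length=max_length)
    solution = select_solution(unique)
    return PipelineResult(
        graph=graph,
        raw_cycle_count=raw.n_raw,
        unique_cycles=unique,
        solution=solution,
    )
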