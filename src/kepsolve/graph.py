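"""Weighted compatibility digraph over donor-recipient pairs.

Vertex ``i`` is pair ``i`` (0-based, contiguous).  Entry ``(i, j)`` of the
adjacency matrix is the aggregated edge weight of "donor of pair i donates
to recipient of pair j"; 0 encodes absence of the edge and the diagonal is
always 0 (a pair registered for exchange is by definition incompatible
internally, and self-loops are meaningless in a cycle exchange).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import medical
from .hla import ValidationError
from .medical import Pair, WeightConfig

__all__ = ["CompatibilityGraph", "compute_compatibility_graph"]


@dataclass(frozen=True)
class CompatibilityGraph:
    """n x n non-negative integer weighted adjacency matrix."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"adjacency matrix must be square, got {w.shape}")
        if (w < 0).any():
            raise ValidationError("edge weights must be non-negative")
        if np.diagonal(w).any():
            raise ValidationError("diagonal entries must be 0")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def compute_compatibility_graph(pairs: list[Pair], cfg: WeightConfig) -> CompatibilityGraph:
    """Evaluate all six medical criteria for every ordered pair of vertices.

    ``weights[i, j] = edge_weight(donor_i, recipient_j)`` for ``i != j``.
    Requires at least two pairs with contiguous 0-based ids.
    """
    if len(pairs) < 2:
        raise ValidationError("need at least 2 donor-recipient pairs")
    ids = sorted(p.pair_id for p in pairs)
    if ids != list(range(len(pairs))):
        raise ValidationError(
            f"pair ids must be contiguous 0..{len(pairs) - 1}, got {ids}"
        )
    by_id = {p.pair_id: p for p in pairs}
    n = len(pairs)
    w = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # module-level lookup kept so instrumentation can wrap edge_weight
            w[i, j] = medical.edge_weight(by_id[i].donor, by_id[j].recipient, cfg)
    return CompatibilityGraph(weights=w)
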