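"""Closed-form circuit and communication cost model.

The garbled-circuit cost convention: an AND gate costs 1.5*kappa bits of
communication (kappa the symmetric security parameter, default 128), XOR
and NOT are free, an OR costs as one AND, a MUX costs as one AND.  The
closed forms below instantiate, verbatim, the per-phase gate counts of the
four pipeline phases:

* crossmatch subprotocol — ``2 * |HLA|`` AND gates at circuit depth
  ``log2(|HLA|) + 1`` (|HLA| SIMD antigen/antibody comparisons plus an
  OR reduction tree and one inversion);
* graph construction — the crossmatch circuit plus 5 multiplications,
  5 additions, 1 comparison, 1 AND and 1 MUX, all run once per ordered
  pair of vertices (``|pairs|^2`` invocations);
* cycle counting — a naive adjacency-matrix multiplication:
  ``|pairs|^3`` multiplications and ``|pairs|^3 - |pairs|^2`` additions,
  plus ``|pairs|^2`` comparisons and MUX gates to threshold the weighted
  matrix (the printed multiplication count covers one matrix product, the
  cycle-length-2 case);
* cycle evaluation (dedup + top-k sort) and solution evaluation (greedy
  disjoint packing) — polynomial formulas in the raw cycle count
  ``|cycles|``, the unique count ``|unique|`` and the cycle length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = ["PhaseCost", "CostReport", "closed_form_costs", "DEFAULT_KAPPA"]

DEFAULT_KAPPA = 128
DEFAULT_BITLENGTH = 32

#: Yao-style communication per AND-equivalent gate, in bits.
COMM_BITS_PER_AND = lambda kappa: 1.5 * kappa  # noqa: E731


@dataclass
class PhaseCost:
    """Gate, comparison and communication tallies for one pipeline phase."""

    and_gates: int = 0
    or_gates: int = 0
    mux_gates: int = 0
    comparisons: int = 0
    multiplications: int = 0
    additions: int = 0
    conversions_a2b: int = 0
    conversions_b2a: int = 0
    depth: float = 0.0
    comm_bits: float = 0.0

    @property
    def and_equivalents(self) -> int:
        """Boolean AND-equivalent gates (AND + OR + MUX; XOR/NOT free)."""
        return self.and_gates + self.or_gates + self.mux_gates

    def as_dict(self) -> dict:
        return {
            "and_gates": self.and_gates,
            "or_gates": self.or_gates,
            "mux_gates": self.mux_gates,
            "comparisons": self.comparisons,
            "multiplications": self.multiplications,
            "additions": self.additions,
            "conversions_a2b": self.conversions_a2b,
            "conversions_b2a": self.conversions_b2a,
            "depth": self.depth,
            "comm_bits": self.comm_bits,
        }


@dataclass
class CostReport:
    """Per-phase cost records plus audit metadata of a (simulated) run."""

    phases: dict[str, PhaseCost] = field(default_factory=dict)
    kappa: int = DEFAULT_KAPPA
    bitlength: int = DEFAULT_BITLENGTH
    audit_violations: int = 0
    declassified_labels: tuple[str, ...] = ()
    #: scalar public outputs of the run (e.g. the revealed raw cycle count)
    public_outputs: dict = field(default_factory=dict)

    def phase(self, name: str) -> PhaseCost:
        return self.phases.setdefault(name, PhaseCost())

    @property
    def total_comm_bits(self) -> float:
        return sum(p.comm_bits for p in self.phases.values())

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "bitlength": self.bitlength,
            "audit_violations": self.audit_violations,
            "declassified": list(self.declassified_labels),
            "public_outputs": dict(self.public_outputs),
            "total_comm_bits": self.total_comm_bits,
            "phases": {k: v.as_dict() for k, v in self.phases.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.as_dict(), indent=2, **kw)


def _yao_comm(p: PhaseCost, kappa: int) -> float:
    return COMM_BITS_PER_AND(kappa) * p.and_equivalents


def closed_form_costs(
    n_pairs: int,
    hla_size: int = 50,
    L: int = 2,
    n_cycles: int = 0,
    n_unique: int = 0,
    k: int | None = None,
    kappa: int = DEFAULT_KAPPA,
    bitlength: int = DEFAULT_BITLENGTH,
) -> CostReport:
    """Instantiate the printed per-phase cost formulas.

    ``n_cycles`` is the raw (duplicate-inclusive) cycle count and
    ``n_unique`` the deduplicated count; both are public after the cycle-
    computation phase, so the closed forms of the later phases can be
    evaluated once they are known.  Communication is charged at
    ``1.5 * kappa`` bits per boolean AND-equivalent gate.
    """
    for name, v in (("n_pairs", n_pairs), ("hla_size", hla_size),
                    ("n_cycles", n_cycles), ("n_unique", n_unique)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")

    report = CostReport(kappa=kappa, bitlength=bitlength)
    np2 = n_pairs ** 2

    # -- phase 1a: crossmatch circuit, per invocation ----------------------
    match = report.phase("match_hla")
    match.and_gates = 2 * hla_size
    match.depth = math.log2(hla_size) + 1 if hla_size else 0.0

    # -- phase 1b: graph construction over all ordered pairs ---------------
    build = report.phase("graph_build")
    build.and_gates = (match.and_gates + 1) * np2
    build.multiplications = 5 * np2
    build.additions = 5 * np2
    build.comparisons = np2
    build.mux_gates = np2
    build.depth = match.depth

    # -- phase 2: cycle counting via matrix power ---------------------------
    count = report.phase("cycle_computation")
    count.multiplications = n_pairs ** 3
    count.additions = n_pairs ** 3 - np2
    count.comparisons = np2
    count.mux_gates = np2

    # -- phase 3: dedup + top-k ranking of the raw cycle list ---------------
    ev = report.phase("cycle_evaluation")
    c, u = n_cycles, n_unique
    ev.comparisons = c * (u + (c + 1) * L * (L - 1))
    ev.and_gates = c * (c + 1) * L * (L - 1)
    ev.or_gates = c * (c + 1) * (L - 1)
    ev.mux_gates = c * u * (1 + L) + c

    # -- phase 4: greedy disjoint-set selection ------------------------------
    sol = report.phase("solution_evaluation")
    sol.additions = u ** 2
    sol.comparisons = u ** 2 * L ** 2 + u
    sol.mux_gates = 4 * u ** 2 + u
    sol.or_gates = u ** 2 * L ** 2

    for p in report.phases.values():
        p.comm_bits = _yao_comm(p, kappa)
    return report
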