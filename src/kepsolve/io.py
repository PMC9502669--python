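"""Cohort, matrix, cycle-list and solution serialization.

Cohorts travel as JSON (inspectable and diffable), the compatibility matrix
as CSV with a header row of pair ids.  Schema violations raise
:class:`~kepsolve.hla.ValidationError` naming the offending field.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from .cycles import Cycle, CycleList
from .graph import CompatibilityGraph
from .hla import DEFAULT_CATALOGUE, LOCUS_GROUPS, HLACatalogue, ValidationError
from .medical import DonorProfile, Pair, RecipientProfile, WeightConfig
from .selection import Solution

__all__ = [
    "read_cohort", "write_cohort", "cohort_to_dict", "cohort_from_dict",
    "write_matrix_csv", "read_matrix_csv",
    "cycles_to_json", "solution_to_dict", "write_solution",
    "load_weight_config",
]


def _person_dict(p) -> dict:
    out = {
        "hla": {g: sorted(p.antigens.get(g, ())) for g in LOCUS_GROUPS},
        "abo": p.abo,
        "age": p.age,
        "sex": p.sex,
        "weight_kg": p.weight_kg,
    }
    if isinstance(p, RecipientProfile):
        out["antibodies"] = sorted(p.antibodies)
    return out


def cohort_to_dict(pairs: list[Pair]) -> dict:
    return {
        "pairs": [
            {
                "pair_id": p.pair_id,
                "donor": _person_dict(p.donor),
                "recipient": _person_dict(p.recipient),
            }
            for p in sorted(pairs, key=lambda q: q.pair_id)
        ]
    }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ValidationError(f"missing field {key!r} in {where}")
    return d[key]


def _parse_person(d: dict, where: str, recipient: bool,
                  catalogue: HLACatalogue):
    if not isinstance(d, dict):
        raise ValidationError(f"{where} must be an object")
    hla = _require(d, "hla", where)
    if not isinstance(hla, dict):
        raise ValidationError(f"field 'hla' in {where} must be an object")
    antigens = {g: frozenset(hla.get(g, ())) for g in LOCUS_GROUPS}
    kwargs = dict(
        antigens=antigens,
        abo=_require(d, "abo", where),
        age=_require(d, "age", where),
        sex=_require(d, "sex", where),
        weight_kg=_require(d, "weight_kg", where),
        catalogue=catalogue,
    )
    if not recipient:
        return DonorProfile(**kwargs)
    if "antibodies" in d:
        antibodies = frozenset(d["antibodies"])
    else:
        warnings.warn(
            f"{where} has no 'antibodies' field; defaulting to an empty panel",
            stacklevel=3,
        )
        antibodies = frozenset()
    return RecipientProfile(antibodies=antibodies, **kwargs)


def cohort_from_dict(data: dict,
                     catalogue: HLACatalogue = DEFAULT_CATALOGUE) -> list[Pair]:
    if not isinstance(data, dict) or "pairs" not in data:
        raise ValidationError("cohort JSON must be an object with a 'pairs' field")
    pairs = []
    for i, entry in enumerate(data["pairs"]):
        where = f"pairs[{i}]"
        pid = _require(entry, "pair_id", where)
        if not isinstance(pid, int) or pid < 0:
            raise ValidationError(f"field 'pair_id' in {where} must be a non-negative int")
        donor = _parse_person(_require(entry, "donor", where),
                              f"{where}.donor", recipient=False, catalogue=catalogue)
        recip = _parse_person(_require(entry, "recipient", where),
                              f"{where}.recipient", recipient=True, catalogue=catalogue)
        pairs.append(Pair(pair_id=pid, donor=donor, recipient=recip))
    ids = [p.pair_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate pair_id values in cohort")
    return pairs


def write_cohort(pairs: list[Pair], path) -> None:
    Path(path).write_text(json.dumps(cohort_to_dict(pairs), indent=2) + "\n")


def read_cohort(path, catalogue: HLACatalogue = DEFAULT_CATALOGUE) -> list[Pair]:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed cohort JSON in {path}: {exc}") from exc
    return cohort_from_dict(data, catalogue)


def write_matrix_csv(graph: CompatibilityGraph, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id"] + list(range(graph.n)))
        for i, row in enumerate(graph.weights):
            writer.writerow([i] + [int(x) for x in row])


def read_matrix_csv(path) -> CompatibilityGraph:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    body = [[int(x) for x in row[1:]] for row in rows[1:]]
    return CompatibilityGraph(weights=np.array(body, dtype=np.int64))


def cycles_to_json(cl: CycleList) -> dict:
    return {
        "n_raw": cl.n_raw,
        "n_unique": cl.n_unique,
        "k": cl.k,
        "cycles": [
            {"vertices": list(c.vertices), "weight": c.weight} for c in cl.cycles
        ],
    }


def solution_to_dict(sol: Solution) -> dict:
    return {
        "total_weight": sol.total_weight,
        "cycles": [
            {"vertices": list(c.vertices), "weight": c.weight} for c in sol.cycles
        ],
        "assignments": {str(r): d for r, d in sorted(sol.assignments().items())},
    }


def write_solution(sol: Solution, path) -> None:
    Path(path).write_text(json.dumps(solution_to_dict(sol), indent=2) + "\n")


_WEIGHT_KEYS = {
    "w", "baseline", "bins_hla", "scores_abo", "scores_age",
    "scores_sex", "scores_weight", "weight_margin_kg",
}


def load_weight_config(path) -> WeightConfig:
    """Weight configuration from a YAML or JSON file (keys as in WeightConfig)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError("weight config must be a mapping")
    unknown = set(data) - _WEIGHT_KEYS
    if unknown:
        raise ValidationError(f"unknown weight-config field {sorted(unknown)[0]!r}")
    for key in ("bins_hla", "scores_abo", "scores_age", "scores_sex", "scores_weight"):
        if key in data:
            data[key] = tuple(data[key])
    return WeightConfig(**data)
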