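"""Seeded synthetic donor-recipient cohorts.

Generates exchange pools with the statistical structure the pipeline
assumes: diploid antigen draws per locus group (two uniform draws with
replacement, deduplicated, so homozygosity is allowed), a panel-reactive
antibody (PRA) model in which the recipient holds an antibody against each
catalogue antigen independently with probability ``pra`` (excluding the
recipient's own antigens), categorical ABO frequencies, uniform ages,
truncated-normal body weights and a Bernoulli sex draw.

Default distribution parameters are plausible placeholders, not published
cohort statistics; all are configurable.  Body weights are drawn as whole
kilograms so the integer ring encoding of the secret-sharing backend is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hla import DEFAULT_CATALOGUE, LOCUS_GROUPS, HLACatalogue, ValidationError
from .medical import DonorProfile, Pair, RecipientProfile

__all__ = ["CohortParams", "generate_cohort", "engineered_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class CohortParams:
    """Generator knobs for a synthetic exchange pool."""

    n_pairs: int
    seed: int = 0
    #: probability a recipient holds an antibody against any given antigen
    pra: float = 0.10
    abo_freqs: dict[str, float] = field(
        default_factory=lambda: {"O": 0.43, "A": 0.40, "B": 0.12, "AB": 0.05}
    )
    age_range: tuple[int, int] = (18, 75)
    weight_mean: float = 80.0
    weight_sd: float = 15.0
    weight_bounds: tuple[float, float] = (40.0, 150.0)
    sex_prob_male: float = 0.5
    catalogue: HLACatalogue = field(default=DEFAULT_CATALOGUE, repr=False)

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValidationError(f"n_pairs must be >= 2, got {self.n_pairs}")
        probs = [self.pra, self.sex_prob_male, *self.abo_freqs.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability out of [0, 1]: {p}")
        if set(self.abo_freqs) != {"O", "A", "B", "AB"}:
            raise ValidationError("abo_freqs must cover exactly O, A, B, AB")
        if abs(sum(self.abo_freqs.values()) - 1.0) > 1e-9:
            raise ValidationError("abo_freqs must sum to 1")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 1:
            raise ValidationError(f"invalid age_range {self.age_range}")
        if self.weight_bounds[0] <= 0 or self.weight_bounds[0] > self.weight_bounds[1]:
            raise ValidationError(f"invalid weight_bounds {self.weight_bounds}")


def _draw_antigens(rng: np.random.Generator, catalogue: HLACatalogue):
    """Two uniform draws with replacement per locus group, deduplicated."""
    return {
        g: frozenset(rng.choice(catalogue.groups[g], size=2, replace=True))
        for g in LOCUS_GROUPS
    }


def _draw_person(rng: np.random.Generator, p: CohortParams):
    abo_names = list(p.abo_freqs)
    abo = str(rng.choice(abo_names, p=[p.abo_freqs[g] for g in abo_names]))
    age = int(rng.integers(p.age_range[0], p.age_range[1] + 1))
    sex = "M" if rng.random() < p.sex_prob_male else "F"
    lo, hi = p.weight_bounds
    weight = float(np.clip(rng.normal(p.weight_mean, p.weight_sd), lo, hi))
    return _draw_antigens(rng, p.catalogue), abo, age, sex, float(round(weight))


def generate_cohort(params: CohortParams) -> list[Pair]:
    """Draw a cohort of incompatible donor-recipient pairs, deterministically.

    The recipient's antibody panel is an independent Bernoulli(``pra``) draw
    over the catalogue antigens, excluding the recipient's own antigens.
    """
    rng = np.random.default_rng(params.seed)
    all_codes = params.catalogue.all_codes
    pairs: list[Pair] = []
    for pid in range(params.n_pairs):
        d_ant, d_abo, d_age, d_sex, d_wt = _draw_person(rng, params)
        r_ant, r_abo, r_age, r_sex, r_wt = _draw_person(rng, params)
        own = frozenset().union(*r_ant.values())
        hits = rng.random(len(all_codes)) < params.pra
        antibodies = frozenset(
            code for code, hit in zip(all_codes, hits) if hit and code not in own
        )
        pairs.append(
            Pair(
                pair_id=pid,
                donor=DonorProfile(
                    antigens=d_ant, abo=d_abo, age=d_age, sex=d_sex,
                    weight_kg=d_wt, catalogue=params.catalogue,
                ),
                recipient=RecipientProfile(
                    antigens=r_ant, antibodies=antibodies, abo=r_abo,
                    age=r_age, sex=r_sex, weight_kg=r_wt,
                    catalogue=params.catalogue,
                ),
            )
        )
    return pairs


FIXTURE_NAMES = ("two_cycle", "triangle", "star_conflict", "no_match")


def _person_kwargs(antigen_a: str, **overrides):
    base = dict(
        antigens={"A": frozenset({antigen_a})},
        abo="O", age=40, sex="M", weight_kg=80.0,
    )
    base.update(overrides)
    return base


def _fixture_pairs(donor_tags, blocked_edges, tweaks=None) -> list[Pair]:
    """Pairs whose only graph structure comes from engineered antibodies.

    ``donor_tags[i]`` is a unique A-locus antigen identifying donor ``i``;
    recipient ``j`` holds antibodies against every donor whose edge ``i -> j``
    must not exist.
    """
    n = len(donor_tags)
    tweaks = tweaks or {}
    pairs = []
    for j in range(n):
        antibodies = frozenset(
            donor_tags[i] for i in range(n) if (i, j) in blocked_edges
        )
        d_kw = _person_kwargs(donor_tags[j], **tweaks.get(("d", j), {}))
        r_kw = _person_kwargs("A66", **tweaks.get(("r", j), {}))
        pairs.append(
            Pair(
                pair_id=j,
                donor=DonorProfile(**d_kw),
                recipient=RecipientProfile(antibodies=antibodies, **r_kw),
            )
        )
    return pairs


def engineered_fixture(name: str) -> list[Pair]:
    """Hand-constructed cohorts realizing known graph topologies.

    * ``two_cycle`` — 2 pairs, both directions compatible (one 2-cycle).
    * ``triangle`` — 3 pairs, the single directed cycle 0 -> 1 -> 2 -> 0.
    * ``star_conflict`` — 4 pairs where the heaviest 2-cycle (0, 1) conflicts
      with two lighter disjoint 2-cycles (0, 3) and (1, 2) whose combined
      weight beats it.
    * ``no_match`` — 2 pairs, every edge excluded by crossmatch.
    """
    tags = ("A23", "A24", "A25", "A26")
    if name == "two_cycle":
        return _fixture_pairs(tags[:2], blocked_edges=set())
    if name == "triangle":
        # keep exactly 0->1, 1->2, 2->0
        blocked = {(0, 2), (1, 0), (2, 1)}
        return _fixture_pairs(tags[:3], blocked_edges=blocked)
    if name == "star_conflict":
        # mutual edges only within {0,1}, {1,2}, {0,3}; degrade the scores of
        # the (1,2) and (0,3) exchanges so the (0,1) 2-cycle is heaviest.
        n = 4
        allowed = {(0, 1), (1, 0), (1, 2), (2, 1), (0, 3), (3, 0)}
        blocked = {
            (i, j) for i in range(n) for j in range(n) if i != j
        } - allowed
        tweaks = {
            # senior, light, female donors at 2 and 3 lower the weight of any
            # edge they provide without touching the (0, 1) cycle.
            ("d", 2): dict(age=70, sex="F", weight_kg=50.0),
            ("d", 3): dict(age=70, sex="F", weight_kg=50.0),
        }
        return _fixture_pairs(tags, blocked_edges=blocked, tweaks=tweaks)
    if name == "no_match":
        blocked = {(0, 1), (1, 0), (0, 0), (1, 1)}
        return _fixture_pairs(tags[:2], blocked_edges=blocked)
    raise ValidationError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
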