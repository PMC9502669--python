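"""Medical compatibility model.

Six criteria determine whether (and how well) the donor of one
donor-recipient pair can give a kidney to the recipient of another:

* **HLA crossmatch** — hard gate.  If the recipient holds an antibody
  against any of the donor's HLA antigens the transplant is excluded and
  the edge weight is 0.
* **HLA mismatch quality** — donor antigens absent from the recipient's own
  antigen set increase rejection risk; the count (capped at two per locus
  group, at most eight total) is binned into four quality levels.
* **ABO blood group** — incompatible groups are a score penalty, not an
  exclusion (grafts across ABO barriers are possible after pre-processing).
* **Age** — junior (<55 y) vs senior (>=55 y); intra-category pairings do
  best, junior donor -> senior recipient next, senior donor -> junior worst.
* **Sex** — same-sex pairings do best, male donor -> female recipient next,
  female donor -> male recipient worst.
* **Weight** — a donor lighter than the recipient raises allograft-loss
  risk; scored as donor_weight >= recipient_weight - margin.

The five quality scores are combined as a dot product with configurable
non-negative integer weights, plus a baseline added to every
crossmatch-compatible edge so compatible edges survive the ``> 0``
adjacency threshold.  All scores/weights are non-negative integers so the
arithmetic secret-sharing backend over Z_{2^l} is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hla import DEFAULT_CATALOGUE, LOCUS_GROUPS, HLACatalogue, ValidationError

__all__ = [
    "DonorProfile",
    "RecipientProfile",
    "Pair",
    "ScoreVector",
    "WeightConfig",
    "CRITERIA",
    "SENIOR_AGE",
    "hla_crossmatch",
    "hla_mismatch_count",
    "hla_mismatch_score",
    "abo_compatible",
    "abo_score",
    "age_score",
    "sex_score",
    "weight_score",
    "score_vector",
    "edge_weight",
]

ABO_GROUPS = ("O", "A", "B", "AB")
SEXES = ("M", "F")
CRITERIA = ("hla_quality", "abo", "age", "sex", "weight")

#: Age (years) at and above which a person counts as senior.
SENIOR_AGE = 55


def _validate_antigens(antigens, catalogue: HLACatalogue, who: str):
    out: dict[str, frozenset[str]] = {}
    for group in LOCUS_GROUPS:
        codes = frozenset(antigens.get(group, ()))
        for code in codes:
            if code not in catalogue.groups.get(group, ()):
                raise ValidationError(
                    f"unknown antigen code {code!r} in {who} group {group}"
                )
        if len(codes) > 2:
            raise ValidationError(
                f"{who} has {len(codes)} antigens at locus {group}; "
                "a person inherits at most two per group"
            )
        out[group] = codes
    return out


def _validate_person(obj, who: str, catalogue: HLACatalogue) -> None:
    object.__setattr__(
        obj, "antigens", _validate_antigens(obj.antigens, catalogue, who)
    )
    if obj.abo not in ABO_GROUPS:
        raise ValidationError(f"invalid ABO blood group {obj.abo!r}")
    if obj.sex not in SEXES:
        raise ValidationError(f"invalid sex {obj.sex!r}")
    if not (isinstance(obj.age, int) and obj.age > 0):
        raise ValidationError(f"age must be a positive integer, got {obj.age!r}")
    if not obj.weight_kg > 0:
        raise ValidationError(f"weight_kg must be positive, got {obj.weight_kg!r}")


@dataclass(frozen=True)
class DonorProfile:
    """A living kidney donor: per-locus antigen sets plus demographics."""

    antigens: dict[str, frozenset[str]]
    abo: str
    age: int
    sex: str
    weight_kg: float
    catalogue: HLACatalogue = field(default=DEFAULT_CATALOGUE, repr=False)

    def __post_init__(self) -> None:
        _validate_person(self, "donor", self.catalogue)

    @property
    def all_antigens(self) -> frozenset[str]:
        return frozenset().union(*self.antigens.values())


@dataclass(frozen=True)
class RecipientProfile:
    """A transplant candidate: antigens, anti-HLA antibody panel, demographics."""

    antigens: dict[str, frozenset[str]]
    antibodies: frozenset[str]
    abo: str
    age: int
    sex: str
    weight_kg: float
    catalogue: HLACatalogue = field(default=DEFAULT_CATALOGUE, repr=False)

    def __post_init__(self) -> None:
        _validate_person(self, "recipient", self.catalogue)
        object.__setattr__(self, "antibodies", frozenset(self.antibodies))
        self.catalogue.validate_codes(self.antibodies, context="antibody")

    @property
    def all_antigens(self) -> frozenset[str]:
        return frozenset().union(*self.antigens.values())


@dataclass(frozen=True)
class Pair:
    """One vertex of the exchange graph: a collapsed donor-recipient pair."""

    pair_id: int
    donor: DonorProfile
    recipient: RecipientProfile

    def __post_init__(self) -> None:
        if not (isinstance(self.pair_id, int) and self.pair_id >= 0):
            raise ValidationError(f"pair_id must be a non-negative int: {self.pair_id!r}")


@dataclass(frozen=True)
class ScoreVector:
    """Per-ordered-pair criterion results: five quality scores + the gate."""

    hla_quality: int
    abo: int
    age: int
    sex: int
    weight: int
    crossmatch: bool

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.hla_quality, self.abo, self.age, self.sex, self.weight)


@dataclass(frozen=True)
class WeightConfig:
    """Criterion score tables and weights, adjustable by medical experts.

    Defaults are the smallest non-negative integers respecting every ordinal
    constraint of the medical model; ``baseline`` guarantees that
    crossmatch-compatible edges carry a strictly positive weight.
    """

    w: dict[str, int] = field(
        default_factory=lambda: {c: 1 for c in CRITERIA}
    )
    baseline: int = 1
    #: scores for 0, 1-2, 3-4, >=5 mismatches (non-increasing).
    bins_hla: tuple[int, int, int, int] = (3, 2, 1, 0)
    #: (compatible, incompatible)
    scores_abo: tuple[int, int] = (1, 0)
    #: (same category, junior donor -> senior recipient, senior -> junior)
    scores_age: tuple[int, int, int] = (2, 1, 0)
    #: (same sex, male donor -> female recipient, female -> male)
    scores_sex: tuple[int, int, int] = (2, 1, 0)
    #: (donor >= recipient - margin, donor lighter)
    scores_weight: tuple[int, int] = (1, 0)
    weight_margin_kg: float = 0.0

    def __post_init__(self) -> None:
        if set(self.w) != set(CRITERIA):
            raise ValidationError(
                f"weights must cover exactly the criteria {CRITERIA}"
            )
        tables = (
            tuple(self.w.values()), (self.baseline,), self.bins_hla,
            self.scores_abo, self.scores_age, self.scores_sex,
            self.scores_weight,
        )
        for table in tables:
            for v in table:
                if not (isinstance(v, int) and v >= 0):
                    raise ValidationError(
                        f"scores and weights must be non-negative integers, got {v!r}"
                    )
        if list(self.bins_hla) != sorted(self.bins_hla, reverse=True):
            raise ValidationError("bins_hla must be non-increasing in mismatch count")
        if self.scores_abo[0] < self.scores_abo[1]:
            raise ValidationError("ABO compatible score must be >= incompatible score")
        for name, t in (("age", self.scores_age), ("sex", self.scores_sex)):
            if not (t[0] >= t[1] >= t[2]):
                raise ValidationError(f"scores_{name} must respect the ordinal ordering")
        if self.scores_weight[0] < self.scores_weight[1]:
            raise ValidationError("weight score for a heavier donor must be >= lighter")

    @property
    def max_edge_weight(self) -> int:
        """Analytic upper bound on any edge weight (used for ring sizing)."""
        maxima = {
            "hla_quality": max(self.bins_hla),
            "abo": max(self.scores_abo),
            "age": max(self.scores_age),
            "sex": max(self.scores_sex),
            "weight": max(self.scores_weight),
        }
        return self.baseline + sum(maxima[c] * self.w[c] for c in CRITERIA)


def hla_crossmatch(
    donor_antigens,
    recipient_antibodies,
    catalogue: HLACatalogue = DEFAULT_CATALOGUE,
) -> bool:
    """Virtual HLA crossmatch: ``True`` means compatible.

    The recipient's anti-HLA antibody panel is tested against the donor's
    antigens; any hit excludes the transplant.
    """
    donor_antigens = frozenset(donor_antigens)
    recipient_antibodies = frozenset(recipient_antibodies)
    catalogue.validate_codes(donor_antigens, context="antigen")
    catalogue.validate_codes(recipient_antibodies, context="antibody")
    return not (donor_antigens & recipient_antibodies)


def hla_mismatch_count(donor_antigens, recipient_antigens) -> int:
    """Number of donor antigens the recipient lacks, per locus group.

    Per group, the count of *distinct* donor antigens absent from the
    recipient's antigen set at the same locus, capped at two per group and
    summed over the four groups (range 0..8).  A donor whose antigens are a
    subset of the recipient's yields 0.
    """
    total = 0
    for group in LOCUS_GROUPS:
        d = frozenset(donor_antigens.get(group, ()))
        r = frozenset(recipient_antigens.get(group, ()))
        total += min(len(d - r), 2)
    return total


def hla_mismatch_score(count: int, cfg: WeightConfig | None = None) -> int:
    """Bin a mismatch count into the configured quality score.

    Bins: 0 mismatches, 1-2, 3-4, >=5 (a count of exactly 5 falls in the
    worst bin).  Non-increasing in the count.
    """
    cfg = cfg or WeightConfig()
    if not 0 <= count <= 8:
        raise ValidationError(f"mismatch count must be in 0..8, got {count}")
    if count == 0:
        return cfg.bins_hla[0]
    if count <= 2:
        return cfg.bins_hla[1]
    if count <= 4:
        return cfg.bins_hla[2]
    return cfg.bins_hla[3]


#: donor group -> groups it can donate to
_ABO_DONATES_TO = {
    "O": frozenset({"O", "A", "B", "AB"}),
    "A": frozenset({"A", "AB"}),
    "B": frozenset({"B", "AB"}),
    "AB": frozenset({"AB"}),
}


def abo_compatible(donor_abo: str, recipient_abo: str) -> bool:
    """ABO blood-group compatibility of donor -> recipient."""
    for g in (donor_abo, recipient_abo):
        if g not in ABO_GROUPS:
            raise ValidationError(f"invalid ABO blood group {g!r}")
    return recipient_abo in _ABO_DONATES_TO[donor_abo]


def abo_score(donor_abo: str, recipient_abo: str, cfg: WeightConfig | None = None) -> int:
    cfg = cfg or WeightConfig()
    ok = abo_compatible(donor_abo, recipient_abo)
    return cfg.scores_abo[0] if ok else cfg.scores_abo[1]


def _is_senior(age: int) -> bool:
    return age >= SENIOR_AGE


def age_score(donor_age: int, recipient_age: int, cfg: WeightConfig | None = None) -> int:
    """Junior/senior category score (same > junior->senior > senior->junior)."""
    cfg = cfg or WeightConfig()
    sd, sr = _is_senior(donor_age), _is_senior(recipient_age)
    if sd == sr:
        return cfg.scores_age[0]
    if not sd and sr:  # junior donor, senior recipient
        return cfg.scores_age[1]
    return cfg.scores_age[2]


def sex_score(donor_sex: str, recipient_sex: str, cfg: WeightConfig | None = None) -> int:
    """Donor/recipient sex pairing score (same > M->F > F->M)."""
    cfg = cfg or WeightConfig()
    for s in (donor_sex, recipient_sex):
        if s not in SEXES:
            raise ValidationError(f"invalid sex {s!r}")
    if donor_sex == recipient_sex:
        return cfg.scores_sex[0]
    if donor_sex == "M":  # male donor -> female recipient
        return cfg.scores_sex[1]
    return cfg.scores_sex[2]


def weight_score(donor_weight: float, recipient_weight: float,
                 cfg: WeightConfig | None = None) -> int:
    cfg = cfg or WeightConfig()
    if donor_weight >= recipient_weight - cfg.weight_margin_kg:
        return cfg.scores_weight[0]
    return cfg.scores_weight[1]


def score_vector(donor: DonorProfile, recipient: RecipientProfile,
                 cfg: WeightConfig) -> ScoreVector:
    """Evaluate all six criteria for an ordered donor -> recipient pairing."""
    mm = hla_mismatch_count(donor.antigens, recipient.antigens)
    return ScoreVector(
        hla_quality=hla_mismatch_score(mm, cfg),
        abo=abo_score(donor.abo, recipient.abo, cfg),
        age=age_score(donor.age, recipient.age, cfg),
        sex=sex_score(donor.sex, recipient.sex, cfg),
        weight=weight_score(donor.weight_kg, recipient.weight_kg, cfg),
        crossmatch=hla_crossmatch(
            donor.all_antigens, recipient.antibodies, donor.catalogue
        ),
    )


def edge_weight(donor: DonorProfile, recipient: RecipientProfile,
                cfg: WeightConfig) -> int:
    """Aggregated transplant-success weight of a donor -> recipient edge.

    Crossmatch failure gates the edge to 0; otherwise the weight is
    ``baseline + sum(score_c * w_c)`` over the five quality criteria.
    """
    sv = score_vector(donor, recipient, cfg)
    if not sv.crossmatch:
        return 0
    return cfg.baseline + sum(
        s * cfg.w[c] for s, c in zip(sv.as_tuple(), CRITERIA)
    )
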