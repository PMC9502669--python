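"""HLA split-antigen catalogue.

The compatibility pipeline types donors and recipients at the split-antigen
level for the four locus groups most relevant to kidney allograft survival:
HLA-A and HLA-B (class I), HLA-DR and HLA-DQ (class II).  The default
catalogue lists the 50 split antigens screened in preparation for kidney
replacement therapy (13 A, 24 B, 8 DR, 5 DQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["HLACatalogue", "DEFAULT_CATALOGUE", "LOCUS_GROUPS", "ValidationError"]

LOCUS_GROUPS = ("A", "B", "DR", "DQ")


class ValidationError(ValueError):
    """Raised when input data violates the cohort / catalogue schema."""


_DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "A": (
        "A23", "A24", "A25", "A26", "A29", "A31", "A32",
        "A33", "A34", "A66", "A68", "A69", "A74",
    ),
    "B": (
        "B38", "B39", "B44", "B45", "B49", "B50", "B51", "B52",
        "B54", "B55", "B56", "B57", "B58", "B60", "B61", "B62",
        "B63", "B64", "B65", "B71", "B72", "B75", "B76", "B77",
    ),
    "DR": ("DR11", "DR12", "DR13", "DR14", "DR15", "DR16", "DR17", "DR18"),
    "DQ": ("DQ5", "DQ6", "DQ7", "DQ8", "DQ9"),
}


@dataclass(frozen=True)
class HLACatalogue:
    """Ordered catalogue of split antigens, grouped by locus.

    Parameters
    ----------
    groups
        Mapping from locus group name (``A``, ``B``, ``DR``, ``DQ``) to the
        ordered tuple of antigen codes observed at that locus.
    """

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, codes in self.groups.items():
            if name not in LOCUS_GROUPS:
                raise ValidationError(f"unknown locus group {name!r}")
            for code in codes:
                if code in seen:
                    raise ValidationError(f"duplicate antigen code {code!r}")
                seen.add(code)

    @property
    def total_size(self) -> int:
        return sum(len(codes) for codes in self.groups.values())

    @property
    def all_codes(self) -> tuple[str, ...]:
        """All antigen codes in catalogue order (group order A, B, DR, DQ)."""
        return tuple(
            code for g in LOCUS_GROUPS for code in self.groups.get(g, ())
        )

    def index_of(self, code: str) -> int:
        try:
            return self.all_codes.index(code)
        except ValueError:
            raise ValidationError(f"unknown antigen code {code!r}") from None

    def group_of(self, code: str) -> str:
        for name, codes in self.groups.items():
            if code in codes:
                return name
        raise ValidationError(f"unknown antigen code {code!r}")

    def validate_codes(self, codes, *, context: str = "antigen") -> None:
        known = set(self.all_codes)
        for code in codes:
            if code not in known:
                raise ValidationError(f"unknown {context} code {code!r}")


DEFAULT_CATALOGUE = HLACatalogue()
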