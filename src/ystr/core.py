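"""Core domain types for Y-STR haplotype analysis.

A Y-STR haplotype is the joint set of alleles (repeat counts) a male carries
across a panel of short-tandem-repeat loci on the non-recombining region of
the Y chromosome.  Because that region is inherited as a block from father to
son, men in the same paternal lineage carry identical haplotypes barring
mutation — which is what makes haplotypes informative about surnames and
founder populations.

The panel here is the 16-locus Yfiler set.  DYS385 is a duplicated locus
typed as an unordered pair of alleles; nominally single-copy loci can also
show duplicated two-allele patterns in some males, so every locus value is a
small multiset (:class:`AlleleSet`) rather than a scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import Iterable, Iterator, Mapping

__all__ = [
    "PANEL",
    "MINIMAL_PANEL",
    "SWGDAM_PANEL",
    "MULTI_COPY_LOCI",
    "LOCUS_ALIASES",
    "canonical_locus",
    "parse_allele",
    "format_allele",
    "AlleleSet",
    "Haplotype",
    "Population",
    "FounderSignature",
]

#: The 16 Yfiler panel loci, in the order the study tables print them.
PANEL: tuple[str, ...] = (
    "DYS456",
    "DYS389I",
    "DYS390",
    "DYS389II",
    "DYS458",
    "DYS19",
    "DYS385",
    "DYS393",
    "DYS391",
    "DYS439",
    "DYS635",
    "DYS392",
    "YGATAH4",
    "DYS437",
    "DYS438",
    "DYS448",
)

#: European minimal haplotype (DYS385 counted as the single unordered-pair locus).
MINIMAL_PANEL: tuple[str, ...] = (
    "DYS19",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS385",
)

#: SWGDAM-recommended extension of the minimal haplotype.
SWGDAM_PANEL: tuple[str, ...] = MINIMAL_PANEL + ("DYS438", "DYS439")

#: Loci typed as an unordered pair of alleles in every male.
MULTI_COPY_LOCI: frozenset[str] = frozenset({"DYS385"})

#: Accepted spellings, mapped to the canonical token.  Y-GATA-H4 appears in
#: the literature under several names; header matching is case-insensitive.
LOCUS_ALIASES: dict[str, str] = {
    "YGATAH": "YGATAH4",
    "Y GATA H4": "YGATAH4",
    "Y-GATA-H4": "YGATAH4",
    "GATAH4": "YGATAH4",
}

_CANONICAL = {name.upper(): name for name in PANEL}


def canonical_locus(name: str) -> str:
    """Resolve a locus name or alias to its canonical panel token.

    Raises
    ------
    KeyError
        If the name is not a panel locus or known alias.
    """
    token = name.strip().upper()
    token = LOCUS_ALIASES.get(token, token)
    if token not in _CANONICAL:
        raise KeyError(
            f"unknown locus {name!r}; panel loci are {', '.join(PANEL)}"
        )
    return _CANONICAL[token]


def parse_allele(token: str | int | float | Decimal) -> Decimal:
    """Parse an allele designation into its numeric repeat count.

    Designations are integers, optionally with a decimal microvariant part
    (``"13.2"`` = 13 full repeats plus a 2-bp partial repeat).  Values are
    normalised so ``13`` and ``13.0`` compare equal.
    """
    if isinstance(token, Decimal):
        value = token
    elif isinstance(token, int):
        value = Decimal(token)
    elif isinstance(token, float):
        value = Decimal(str(token))
    else:
        try:
            value = Decimal(token.strip())
        except InvalidOperation:
            raise ValueError(f"not a numeric allele designation: {token!r}") from None
    if not value.is_finite() or value <= 0:
        raise ValueError(f"allele designation must be a positive number: {token!r}")
    return value.normalize()


def format_allele(value: Decimal) -> str:
    """Render an allele value the way panels print it (``13``, ``13.2``)."""
    if value == value.to_integral_value():
        return str(int(value))
    return str(value.normalize())


@dataclass(frozen=True)
class AlleleSet:
    """Multiset of allele designations observed at one locus in one male.

    Size 1 at an ordinary single-copy locus, 2 at DYS385 or wherever a
    duplicated pattern occurs.  Order-insensitive: ``AlleleSet([14, 11])``
    equals ``AlleleSet([11, 14])``.
    """

    alleles: tuple[Decimal, ...]

    def __init__(self, alleles: Iterable[str | int | float | Decimal]):
        parsed = sorted(parse_allele(a) for a in alleles)
        if not parsed:
            raise ValueError("AlleleSet must contain at least one allele")
        object.__setattr__(self, "alleles", tuple(parsed))

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self) -> Iterator[Decimal]:
        return iter(self.alleles)

    def __contains__(self, allele: object) -> bool:
        try:
            return parse_allele(allele) in self.alleles  # type: ignore[arg-type]
        except (ValueError, TypeError):
            return False

    def __str__(self) -> str:
        return ",".join(format_allele(a) for a in self.alleles)

    def __repr__(self) -> str:
        return f"AlleleSet({str(self)!r})"


@dataclass(frozen=True)
class Haplotype:
    """One male's Y-STR haplotype over the 16-locus panel, plus metadata.

    All 16 panel loci must be present; partial comparisons are expressed by
    masking loci at analysis time, never by dropping them from the record.
    """

    sample_id: str
    locus_values: Mapping[str, AlleleSet]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = {canonical_locus(k): v for k, v in self.locus_values.items()}
        missing = [loc for loc in PANEL if loc not in values]
        if missing:
            raise ValueError(
                f"haplotype {self.sample_id!r} missing panel loci: {', '.join(missing)}"
            )
        object.__setattr__(self, "locus_values", values)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __getitem__(self, locus: str) -> AlleleSet:
        return self.locus_values[canonical_locus(locus)]

    def same_haplotype(self, other: "Haplotype", panel: Iterable[str] = PANEL) -> bool:
        """True iff the two haplotypes are identical over ``panel``."""
        return all(self[loc] == other[loc] for loc in panel)


@dataclass
class Population:
    """Named, ordered collection of haplotypes (a study group or database)."""

    name: str
    members: list[Haplotype]

    def __post_init__(self) -> None:
        self.members = list(self.members)
        seen: set[str] = set()
        for h in self.members:
            if h.sample_id in seen:
                raise ValueError(
                    f"duplicate sample_id {h.sample_id!r} in population {self.name!r}"
                )
            seen.add(h.sample_id)

    @property
    def N(self) -> int:
        return len(self.members)

    @property
    def sample_ids(self) -> list[str]:
        return [h.sample_id for h in self.members]

    def __len__(self) -> int:
        return self.N

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.members)

    def __getitem__(self, sample_id: str) -> Haplotype:
        for h in self.members:
            if h.sample_id == sample_id:
                return h
        raise KeyError(f"no sample {sample_id!r} in population {self.name!r}")


@dataclass(frozen=True)
class FounderSignature:
    """Partial haplotype characteristic of a founding paternal lineage.

    Covers only a subset of panel loci (e.g. the six-locus Dal Riata
    signature, or a four-locus surname footprint).
    """

    name: str
    locus_values: Mapping[str, AlleleSet]

    def __post_init__(self) -> None:
        values = {canonical_locus(k): v for k, v in self.locus_values.items()}
        object.__setattr__(self, "locus_values", values)

    @property
    def loci(self) -> tuple[str, ...]:
        """Signature loci in panel order."""
        return tuple(loc for loc in PANEL if loc in self.locus_values)

    def __getitem__(self, locus: str) -> AlleleSet:
        return self.locus_values[canonical_locus(locus)]

    def __len__(self) -> int:
        return len(self.locus_values)
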