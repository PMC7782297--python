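"""Counting-method frequencies, allele frequencies, and founder-signature
analysis.

The counting method ("frequentist approach") estimates a haplotype's
population frequency as X/N — the number of database samples carrying an
identical haplotype over the compared panel, divided by the database size.
Forensic reports phrase the estimate as "1 in n individuals".

Signature matching classifies samples against a partial founder haplotype
(e.g. the Dal Riata signature) with an optional set of ignored loci;
footprint sharing reports, locus by locus, what fraction of a population
carries exactly the signature's allele set.  Exact multiset equality is
used throughout: a duplicated {15,16} pattern does not count as carrying
a plain 15 in exact mode (carrier mode is available separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Literal, Mapping

from .core import (
    AlleleSet,
    FounderSignature,
    Haplotype,
    Population,
    canonical_locus,
    format_allele,
    parse_allele,
)
from .similarity import _resolve_panel, percent_similarity

__all__ = [
    "FrequencyEstimate",
    "SharingReport",
    "SignatureMatchReport",
    "haplotype_frequency",
    "format_one_in_n",
    "allele_frequency",
    "modal_allele",
    "footprint_sharing",
    "matches_signature",
    "classify_population",
]


@dataclass(frozen=True)
class FrequencyEstimate:
    """Counting-method haplotype frequency: X observations in N samples."""

    X: int
    N: int

    def __post_init__(self) -> None:
        if not 0 <= self.X <= self.N:
            raise ValueError(f"need 0 <= X <= N, got X={self.X}, N={self.N}")

    @property
    def frequency(self) -> float:
        return self.X / self.N

    @property
    def one_in_n(self) -> int | None:
        """Rounded n with frequency ≈ 1/n; None when never observed."""
        if self.X == 0:
            return None
        return round(self.N / self.X)


def haplotype_frequency(
    query: Haplotype,
    pop: Population,
    panel: Iterable[str] | None = None,
) -> FrequencyEstimate:
    """Counting-method frequency of ``query``'s haplotype in ``pop``.

    X counts members identical to the query over the panel (the query
    itself counts if it is a member).
    """
    if pop.N < 1:
        raise ValueError("population must have at least one member")
    loci = _resolve_panel(panel)
    x = sum(
        percent_similarity(query, member, loci).matched_loci == len(loci)
        for member in pop
    )
    return FrequencyEstimate(X=x, N=pop.N)


def format_one_in_n(freq: FrequencyEstimate) -> str:
    """Forensic "1 in n individuals" phrasing of a counting-method estimate."""
    n = freq.one_in_n
    if n is None:
        return "not observed"
    return f"1 in {n}"


def allele_frequency(
    pop: Population,
    locus: str,
    mode: Literal["exact", "carrier"] = "exact",
) -> dict[AlleleSet, float] | dict[Decimal, float]:
    """Per-locus allele frequencies as percentages of N.

    ``exact`` mode keys on whole allele sets (the pair {11,14} is one key;
    a duplicated {15,16} is distinct from {15}); the percentages sum to
    100.  ``carrier`` mode keys on single allele values and counts samples
    carrying that allele anywhere in their set, so percentages can exceed
    100 in total.
    """
    if pop.N < 1:
        raise ValueError("population must have at least one member")
    loc = canonical_locus(locus)
    if mode == "exact":
        counts: dict[AlleleSet, int] = {}
        for h in pop:
            key = h[loc]
            counts[key] = counts.get(key, 0) + 1
        return {k: 100.0 * v / pop.N for k, v in counts.items()}
    elif mode == "carrier":
        ccounts: dict[Decimal, int] = {}
        for h in pop:
            for allele in set(h[loc].alleles):
                ccounts[allele] = ccounts.get(allele, 0) + 1
        return {k: 100.0 * v / pop.N for k, v in ccounts.items()}
    raise ValueError(f"mode must be 'exact' or 'carrier', got {mode!r}")


def modal_allele(pop: Population, locus: str) -> tuple[AlleleSet, float]:
    """Most common exact allele set at a locus, with its percentage.

    Ties break toward the smallest allele values (deterministic; the study
    tables have no ties at the loci reported).
    """
    freqs = allele_frequency(pop, locus, mode="exact")
    best = max(freqs.items(), key=lambda kv: (kv[1], [-a for a in kv[0].alleles]))
    return best


@dataclass(frozen=True)
class SharingReport:
    """Per-locus percent of a population exactly sharing a signature's alleles."""

    signature_name: str
    per_locus: Mapping[str, float]
    N: int

    def __getitem__(self, locus: str) -> float:
        return self.per_locus[canonical_locus(locus)]


def footprint_sharing(pop: Population, sig: FounderSignature) -> SharingReport:
    """Percent of ``pop`` whose allele set exactly equals ``sig``'s, per locus.

    Only the signature's loci appear in the report.  Internally consistent
    with exact-mode :func:`allele_frequency` evaluated at the signature's
    allele set.
    """
    if pop.N < 1:
        raise ValueError("population must have at least one member")
    if len(sig) == 0:
        raise ValueError("signature covers no loci")
    per_locus = {
        loc: 100.0 * sum(h[loc] == sig[loc] for h in pop) / pop.N
        for loc in sig.loci
    }
    return SharingReport(signature_name=sig.name, per_locus=per_locus, N=pop.N)


def matches_signature(
    h: Haplotype,
    sig: FounderSignature,
    ignore: Iterable[str] = (),
) -> bool:
    """True iff every signature locus outside ``ignore`` matches exactly.

    Vacuously true for an empty signature.
    """
    ignored = {canonical_locus(loc) for loc in ignore}
    return all(h[loc] == sig[loc] for loc in sig.loci if loc not in ignored)


@dataclass(frozen=True)
class SignatureMatchReport:
    """Samples in a population consistent with a founder signature."""

    signature_name: str
    ignored_loci: frozenset[str]
    matching_sample_ids: tuple[str, ...]

    @property
    def match_count(self) -> int:
        return len(self.matching_sample_ids)


def classify_population(
    pop: Population,
    sig: FounderSignature,
    ignore: Iterable[str] = (),
) -> SignatureMatchReport:
    """List the members of ``pop`` matching ``sig`` (outside ``ignore``)."""
    ignored = frozenset(canonical_locus(loc) for loc in ignore)
    matching = tuple(
        h.sample_id for h in pop if matches_signature(h, sig, ignored)
    )
    return SignatureMatchReport(
        signature_name=sig.name,
        ignored_loci=ignored,
        matching_sample_ids=matching,
    )
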