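"""Pairwise haplotype comparison and similarity matrices.

The comparison rule is binary per locus: two samples match at a locus iff
their allele multisets are identical.  Both alleles of a DYS385 pair must
agree, and a duplicated pattern at a nominally single-copy locus (e.g.
{15,16} at DYS437) never matches a single allele {15}.  Percent similarity
is the fraction of matching loci over the compared panel, as a percentage.

No mutation-step weighting: a one-repeat difference counts the same as any
other mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import PANEL, AlleleSet, Haplotype, Population, canonical_locus

__all__ = [
    "locus_match",
    "percent_similarity",
    "similarity_matrix",
    "identity_classes",
    "SimilarityResult",
    "SimilarityMatrix",
    "IdentityClasses",
]


def locus_match(a: AlleleSet, b: AlleleSet) -> bool:
    """True iff the two allele multisets are identical."""
    return a == b


def _round2(value: float) -> float:
    # half-up, not banker's: all reachable 16-locus values are exact anyway
    return float(Decimal(str(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class SimilarityResult:
    """Outcome of one pairwise haplotype comparison."""

    sample_a: str
    sample_b: str
    matched_loci: int
    compared_loci: int

    @property
    def percent(self) -> float:
        """100 × matched/compared, rounded half-up to 2 decimals."""
        return _round2(100.0 * self.matched_loci / self.compared_loci)


def _resolve_panel(panel: Iterable[str] | None) -> tuple[str, ...]:
    if panel is None:
        return PANEL
    resolved = tuple(canonical_locus(loc) for loc in panel)
    if not resolved:
        raise ValueError("panel must contain at least one locus")
    return resolved


def percent_similarity(
    h1: Haplotype,
    h2: Haplotype,
    panel: Iterable[str] | None = None,
    mask: Iterable[str] = (),
) -> SimilarityResult:
    """Compare two haplotypes locus by locus over ``panel``.

    ``mask`` removes loci from the comparison, shrinking the denominator
    (a masked locus is neither a match nor a mismatch).  Symmetric in its
    arguments.
    """
    loci = _resolve_panel(panel)
    masked = {canonical_locus(loc) for loc in mask}
    compared = [loc for loc in loci if loc not in masked]
    if not compared:
        raise ValueError("all panel loci are masked; nothing to compare")
    matched = sum(locus_match(h1[loc], h2[loc]) for loc in compared)
    return SimilarityResult(h1.sample_id, h2.sample_id, matched, len(compared))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric matrix of pairwise percent similarities."""

    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (N, N), percent

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )

    def lower_triangle(self) -> pd.DataFrame:
        """Lower-triangle view (diagonal and above blanked), the layout the
        study tables use."""
        df = self.to_dataframe().copy()
        n = len(self.sample_ids)
        arr = df.to_numpy(dtype=object)
        for i in range(n):
            for j in range(i, n):
                arr[i, j] = ""
        return pd.DataFrame(arr, index=df.index, columns=df.columns)


def similarity_matrix(
    pop: Population,
    panel: Iterable[str] | None = None,
    mask: Iterable[str] = (),
) -> SimilarityMatrix:
    """All-pairs percent similarity over a population (diagonal = 100)."""
    if pop.N < 1:
        raise ValueError("population must have at least one member")
    loci = _resolve_panel(panel)
    n = pop.N
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            p = percent_similarity(pop.members[i], pop.members[j], loci, mask).percent
            values[i, j] = values[j, i] = p
    return SimilarityMatrix(tuple(pop.sample_ids), values)


@dataclass(frozen=True)
class IdentityClasses:
    """Partition of a population's sample ids by full-haplotype identity."""

    classes: tuple[tuple[str, ...], ...]

    @property
    def n_distinct(self) -> int:
        """Number of distinct haplotypes in the population."""
        return len(self.classes)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.classes)

    def class_of(self, sample_id: str) -> tuple[str, ...]:
        for c in self.classes:
            if sample_id in c:
                return c
        raise KeyError(sample_id)


def identity_classes(
    pop: Population, panel: Iterable[str] | None = None
) -> IdentityClasses:
    """Group samples whose haplotypes are identical over ``panel``.

    Two samples fall in one class iff their percent similarity is 100 over
    the panel.  Classes preserve population order.
    """
    if pop.N < 1:
        raise ValueError("population must have at least one member")
    loci = _resolve_panel(panel)
    classes: list[list[Haplotype]] = []
    for h in pop.members:
        for cls in classes:
            if h.same_haplotype(cls[0], loci):
                cls.append(h)
                break
        else:
            classes.append([h])
    return IdentityClasses(
        tuple(tuple(m.sample_id for m in cls) for cls in classes)
    )
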