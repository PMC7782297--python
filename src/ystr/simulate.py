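"""Synthetic surname-study generator under a stepwise mutation model.

Y-STR alleles mutate predominantly by gaining or losing a single repeat
unit.  The simulator embodies the analysis's core assumption — that males
in one paternal line are identical by descent barring mutation — by
propagating a founder haplotype through independent father-to-son chains:
per meiosis, each allele copy mutates with its locus rate and steps ±1
repeat with equal probability (floor at one repeat, where the step is
forced upward).  Each descendant is an independent chain from the founder
(star genealogy), which is sufficient to produce the similarity gradients
a surname study interprets; a branching shared pedigree is out of scope.

Unrelated samples are drawn locus-by-locus from allele-frequency tables,
standing in for a randomly sampled control population.  DYS385 draws two
copies independently.

Default mutation rate: 0.002 per locus per generation, the order of
magnitude typical for Y-STR loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    MULTI_COPY_LOCI,
    PANEL,
    AlleleSet,
    Haplotype,
    Population,
    canonical_locus,
    parse_allele,
)

__all__ = [
    "MutationModel",
    "StudyDesign",
    "SurnameStudy",
    "simulate_lineage",
    "simulate_unrelated",
    "simulate_surname_study",
    "empirical_allele_frequencies",
]

DEFAULT_MUTATION_RATE = 0.002


@dataclass(frozen=True)
class MutationModel:
    """Single-step symmetric stepwise mutation model.

    ``per_locus_rate`` maps each panel locus to its mutation probability
    per meiosis; unlisted loci take ``default_rate``.  Multi-copy loci
    mutate each allele copy independently.
    """

    per_locus_rate: Mapping[str, float] = field(default_factory=dict)
    default_rate: float = DEFAULT_MUTATION_RATE

    def __post_init__(self) -> None:
        rates = {canonical_locus(k): float(v) for k, v in self.per_locus_rate.items()}
        object.__setattr__(self, "per_locus_rate", rates)
        for locus, rate in [*rates.items(), ("default", self.default_rate)]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"mutation rate for {locus} outside [0, 1]: {rate}")

    def rate(self, locus: str) -> float:
        return self.per_locus_rate.get(canonical_locus(locus), self.default_rate)

    @classmethod
    def uniform(cls, mu: float) -> "MutationModel":
        return cls(default_rate=mu)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _split_copies(alleles: Sequence[Decimal]) -> tuple[np.ndarray, list[Decimal]]:
    """Decompose allele values into integer repeat counts + fixed fractional
    (microvariant) parts; mutation steps act on the integer part only."""
    ints = np.array([int(a) for a in alleles], dtype=np.int64)
    fracs = [a - int(a) for a in alleles]
    return ints, fracs


def simulate_lineage(
    founder: Haplotype,
    generations: int,
    model: MutationModel | None = None,
    n_descendants: int = 1,
    seed: int | np.random.Generator | None = None,
) -> Population:
    """Simulate ``n_descendants`` males, each ``generations`` meioses below
    the founder along an independent paternal chain.

    With ``generations=0`` or a zero mutation rate, every descendant equals
    the founder.  Deterministic for a fixed integer seed.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if n_descendants < 1:
        raise ValueError("n_descendants must be >= 1")
    model = model or MutationModel()
    rng = _as_rng(seed)

    # per locus: (n_descendants, n_copies) integer repeat counts
    members_loci: list[dict[str, AlleleSet]] = [dict() for _ in range(n_descendants)]
    for locus in PANEL:
        rate = model.rate(locus)
        ints0, fracs = _split_copies(founder[locus].alleles)
        counts = np.tile(ints0, (n_descendants, 1))
        for _ in range(generations):
            mutates = rng.random(counts.shape) < rate
            steps = rng.choice((-1, 1), size=counts.shape)
            # floor at one repeat: a down-step at 1 is forced up
            steps = np.where((counts == 1) & mutates, 1, steps)
            counts = counts + np.where(mutates, steps, 0)
        for d in range(n_descendants):
            members_loci[d][locus] = AlleleSet(
                Decimal(int(counts[d, c])) + fracs[c] for c in range(len(fracs))
            )

    members = [
        Haplotype(
            sample_id=f"{founder.sample_id}-D{d + 1}",
            locus_values=members_loci[d],
            metadata={"founder": founder.sample_id, "generations": str(generations)},
        )
        for d in range(n_descendants)
    ]
    return Population(name=f"{founder.sample_id}_lineage", members=members)


def empirical_allele_frequencies(
    pop: Population,
) -> dict[str, dict[Decimal, float]]:
    """Per-copy allele frequency tables observed in a population.

    Counts every allele copy (both members of a DYS385 pair, both alleles
    of a duplicated pattern) and normalises per locus — the natural input
    for :func:`simulate_unrelated`.
    """
    tables: dict[str, dict[Decimal, float]] = {}
    for locus in PANEL:
        counts: dict[Decimal, int] = {}
        total = 0
        for h in pop:
            for allele in h[locus].alleles:
                counts[allele] = counts.get(allele, 0) + 1
                total += 1
        tables[locus] = {a: c / total for a, c in counts.items()}
    return tables


def simulate_unrelated(
    freqs: Mapping[str, Mapping[Decimal | int | float | str, float]],
    n: int,
    seed: int | np.random.Generator | None = None,
    id_prefix: str = "U",
    name: str = "unrelated",
) -> Population:
    """Draw ``n`` mutually unrelated haplotypes from allele-frequency tables.

    Each locus is drawn independently from its table; DYS385 draws two
    copies.  Frequencies per locus must sum to 1 (tolerance 1e-6).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    tables: dict[str, tuple[list[Decimal], np.ndarray]] = {}
    for locus in PANEL:
        raw = freqs.get(canonical_locus(locus)) if canonical_locus(locus) in freqs else None
        if raw is None:
            for key in freqs:
                if canonical_locus(key) == locus:
                    raw = freqs[key]
                    break
        if not raw:
            raise ValueError(f"empty or missing frequency table for locus {locus}")
        alleles = [parse_allele(a) for a in raw]
        probs = np.array([float(p) for p in raw.values()])
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"frequencies at {locus} sum to {probs.sum():.6f}, expected 1"
            )
        tables[locus] = (alleles, probs / probs.sum())

    members = []
    for i in range(n):
        locus_values = {}
        for locus in PANEL:
            alleles, probs = tables[locus]
            n_copies = 2 if locus in MULTI_COPY_LOCI else 1
            idx = rng.choice(len(alleles), size=n_copies, p=probs)
            locus_values[locus] = AlleleSet(alleles[j] for j in idx)
        members.append(Haplotype(f"{id_prefix}{i + 1}", locus_values))
    return Population(name=name, members=members)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a synthetic surname study.

    ``founders`` lists (founder haplotype, cluster size, pedigree depth in
    generations); ``n_unrelated`` unrelated samples are drawn from
    ``allele_freqs`` (explicit tables, or a Population to take empirical
    per-copy frequencies from).
    """

    founders: tuple[tuple[Haplotype, int, int], ...]
    n_unrelated: int = 0
    allele_freqs: Mapping[str, Mapping] | Population | None = None
    model: MutationModel = field(default_factory=MutationModel)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "founders", tuple(self.founders))
        for founder, size, depth in self.founders:
            if size < 1:
                raise ValueError(f"cluster size for {founder.sample_id} must be >= 1")
            if depth < 0:
                raise ValueError(f"pedigree depth for {founder.sample_id} must be >= 0")
        if self.n_unrelated > 0 and self.allele_freqs is None:
            raise ValueError("n_unrelated > 0 requires allele_freqs")


@dataclass(frozen=True)
class SurnameStudy:
    """Simulated study: one population per founder cluster plus unrelateds."""

    clusters: tuple[Population, ...]
    unrelated: Population


def simulate_surname_study(design: StudyDesign) -> SurnameStudy:
    """Generate a full synthetic study, reproducible from ``design.seed``."""
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(len(design.founders) + 1)
    clusters = tuple(
        simulate_lineage(
            founder,
            generations=depth,
            model=design.model,
            n_descendants=size,
            seed=np.random.default_rng(children[i]),
        )
        for i, (founder, size, depth) in enumerate(design.founders)
    )
    freqs = design.allele_freqs
    if isinstance(freqs, Population):
        freqs = empirical_allele_frequencies(freqs)
    if design.n_unrelated > 0:
        unrelated = simulate_unrelated(
            freqs, design.n_unrelated, seed=np.random.default_rng(children[-1])
        )
    else:
        unrelated = Population(name="unrelated", members=[])
    return SurnameStudy(clusters=clusters, unrelated=unrelated)
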