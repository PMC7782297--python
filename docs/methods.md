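# Methods

## Data model

A haplotype is a mapping from the 16 Yfiler panel loci (DYS456, DYS389I,
DYS390, DYS389II, DYS458, DYS19, DYS385, DYS393, DYS391, DYS439, DYS635,
DYS392, Y-GATA-H4, DYS437, DYS438, DYS448) to allele *multisets*. Using a
multiset everywhere, rather than a scalar with a special case for DYS385,
lets one representation carry the ordinary single-allele call, the DYS385
unordered pair, and the occasional duplicated pattern at a nominally
single-copy locus (one packaged sample carries {15,16} at DYS437). Allele
designations are decimal repeat counts; microvariants (e.g. 13.2) are
supported and normalised so 13 and 13.0 compare equal. Multisets are
order-insensitive: {11,14} equals {14,11}.

All 16 loci must be present in every record. Partial comparisons are
expressed by masking loci at analysis time, never by dropping them from the
data — this keeps "missing" explicit and auditable. The canonical locus
token for Y-GATA-H4 is `YGATAH4`, with `YGATAH` and `Y GATA H4` accepted as
input aliases (both spellings circulate). Named sub-panels: the European
minimal haplotype (8 loci, with DYS385 counted once as the pair-valued
locus) and the SWGDAM extension (minimal plus DYS438 and DYS439).

## CSV dialect

One row per sample; a required `sample_id` column; one column per locus;
any other columns are free-text metadata and round-trip untouched. Alleles
within a cell are joined by a semicolon (`11;14`) so the file parses
without quoting; a quoted comma-separated cell (`"11,14"`, the convention
printed tables use) is accepted on input. Headers are case-insensitive.
Multi-allele cells are written smallest allele first, making output
byte-deterministic. Reading back a written population reproduces it
exactly; this round-trip is property-tested over randomly generated
populations.

## Pairwise similarity

Two haplotypes match at a locus iff their allele multisets are identical —
both alleles of a DYS385 pair must agree, and a duplicated {15,16} never
matches a single {15}. Percent similarity over a panel is
100 · (matching loci) / (compared loci), rounded half-up to two decimals;
on the full panel every reachable value is an exact multiple of 6.25, so
rounding is cosmetic. A masked locus shrinks the denominator rather than
counting as a mismatch, keeping partial-panel comparisons interpretable.

This binary locus rule was chosen over step-weighted alternatives
(any-shared-allele, Jaccard, stepwise distances) because it is the rule the
published pairwise table of the packaged study data obeys: the discordant
cell is the OB8–OB9 pair (12.50 = 2/16), which only exact multiset equality
reproduces. No mutation-step weighting is offered; a one-repeat difference
counts the same as any other mismatch.

Identity classes partition a population by full-haplotype identity over the
chosen panel; two samples share a class iff their percent similarity is
exactly 100. In the packaged data the ten surname samples collapse to nine
distinct haplotypes (one coincidental identical pair from the same county),
and the control group's known father–son pair shares a class.

## Counting-method frequency

The haplotype frequency estimate is X/N: the number of database members
identical to the query over the compared panel, divided by database size,
with the forensic "1 in n" phrasing where n = round(N/X). A never-observed
haplotype reports an explicit "not observed" marker, never a division. No
confidence intervals and no (X+1)/(N+1) augmentation are applied — the
plain counting estimate is the method implemented; extensions would be
explicit options, off by default.

## Founder signatures

A founder signature is a partial haplotype over any subset of panel loci.
Matching is exact multiset equality at every signature locus outside an
explicit ignore-set. The packaged Dal Riata six-locus signature is stored
exactly as published, including its DYS389II value of 16 — a value outside
the 28–33 range the study tables show at that locus (it is plausibly a
subtracted DYS389b-convention value, since 29 − 13 = 16, but the published
classifications themselves set DYS389II aside rather than reinterpreting
it). Accordingly the shipped Dal Riata classification is run with
`ignore={"DYS389II"}`, which reproduces every published assignment: OB9,
OB11 and I9 across the two study groups, C6 and C7 among the controls.

Footprint sharing reports, locus by locus, the percentage of a population
whose allele multiset exactly equals the signature's. Exact counting was
validated against the published 14-locus O'Brien footprint sharing list: 13
of 14 percentages reproduce, including the discriminating 70% at DYS437
(the duplicated {15,16} sample does not count as a plain 15). The one
exception is DYS385, where the published 80% corresponds to
carrier-counting allele 11 (8/10) while exact pair-counting of {11,14}
gives 40% — no single counting rule reproduces all 14 printed values, so
the package reports exact-mode and documents the discrepancy. Carrier-mode
allele frequencies are available separately for exactly this kind of
question.

Modal-allele ties break toward the smallest allele value — arbitrary but
deterministic; the packaged data contain no ties at the loci reported.

## Stepwise-mutation simulator

The simulator generates the statistical structure the analysis assumes:
patrilineally related clusters mixed with unrelated samples.

**Lineages.** Each descendant is an independent father-to-son chain of
`generations` meioses from the founder (a star genealogy). Per meiosis each
allele copy mutates with its locus rate (default μ = 0.002 per locus per
generation, the order of magnitude of observed Y-STR rates; configurable
per locus) and steps ±1 repeat with equal probability — the single-step
symmetric stepwise mutation model. Repeat counts have a floor at 1, where a
down-step is forced upward; no upper bound is imposed. Multi-copy loci
mutate each copy independently; a microvariant's fractional part rides
along unchanged.

**Unrelated samples** draw each locus independently from an
allele-frequency table (two independent draws for DYS385); per-copy
empirical tables can be derived from any population. Independence across
loci means simulated unrelateds carry no linkage structure — real
populations do (haplogroup correlations), so simulated "uniqueness" rates
are optimistic.

**Determinism.** Every generator takes an integer seed (or a numpy
Generator); a study design reproduces byte-identical serialised output
from its seed, with per-cluster child streams spawned from a seed sequence.

**What passing simulator tests show.** Calibration checks verify per-locus
identity after g generations against the closed-form band
(1−μ)^g ≤ P(unchanged) ≤ (1−μ)^g + C(g,2)·μ² within three Monte-Carlo
standard errors (2 000 descendants, 10 generations), realised allele draws
against their source frequencies (binomial check at n = 5 000), and that
clusters from founders differing at 8+ loci show higher within- than
between-cluster similarity. These validate the machinery on its own model
assumptions; they do not show that the star genealogy, uniform rate, or
single-step model fit any particular real pedigree — branching pedigrees,
multi-step mutations, and locus-specific rate estimates are deliberate
simplifications left out of scope.

## Numerical and interface choices

- Percent rounding is half-up (not banker's) to two decimals.
- Allele values are `decimal.Decimal`, so microvariant arithmetic and
  equality are exact; no floating-point allele keys exist.
- Populations preserve input row order everywhere; classification reports
  list matches in population order.
- Problem sizes in the test suite (2 000-descendant calibration, 5 000-draw
  binomial check, 500 round-trip examples) were chosen as the smallest
  sizes at which the three-standard-error bands are meaningfully narrow.
- The control fixture ships all 22 printed rows; analyses that need a
  subset (e.g. "10 randomly sampled" comparisons) take an explicit subset
  argument rather than guessing an unpublished selection, so no shipped
  result depends on an unreproducible subsample.

## Known limitations

- The binary locus-match rule ignores mutational distance; one repeat and
  ten repeats apart are equally "different".
- Counting-method estimates from N ≤ 22 databases carry large sampling
  error; the package reports the plain estimate without intervals.
- The simulator's star genealogy has no shared internal branches, so
  within-cluster similarity decays faster with depth than in a real
  branching pedigree of the same size.
- External haplotype-database lookups (the "1 in n" values large reference
  databases would give) are out of scope; only the formatting of such
  estimates is provided.
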