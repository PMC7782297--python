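# ystr — Y-STR haplotype analysis for surname and founder-lineage studies

Y-chromosome short tandem repeats (Y-STRs) are inherited as a block from
father to son, so — barring mutation — every male in a paternal lineage
carries the same haplotype. That makes Y-STR haplotypes a natural tool for
surname studies (does a surname trace back to one founding male?), for
classifying samples against ancestral founder signatures (e.g. the Dal
Riata, an early-medieval Gaelic overkingdom), and for forensic "dragnet"
screening, where most unrelated males in a restricted area carry distinct
haplotypes.

`ystr` implements the complete analysis stack for such a study over the
16-locus Yfiler panel, for forensic geneticists and genetic genealogists:

- **Data model and I/O** — haplotypes as per-locus allele *multisets*
  (DYS385 is typed as an unordered pair; duplicated patterns such as
  {15,16} at a nominally single-copy locus are first-class), with a
  documented CSV dialect and packaged study data: an O'Brien surname group
  (N=10), a general Irish group (N=10), and a control group (N=22).
- **Pairwise similarity** — the percent of panel loci at which two
  haplotypes carry identical allele multisets,
  `100 · matched / compared`, plus full similarity matrices and identity
  classes (groups of samples sharing one haplotype).
- **Counting-method frequency** — the ISFG "frequentist approach":
  a haplotype's frequency is X/N, observations over database size,
  reported forensically as "1 in n individuals".
- **Founder signatures** — matching against partial haplotypes
  (Dal Riata, the O'Brien surname footprint, the Sykes footprint) with an
  ignore-set for discrepant loci, and per-locus footprint sharing
  percentages.
- **Stepwise-mutation simulator** — synthetic surname studies: patrilineal
  clusters propagated from founder haplotypes under a single-step symmetric
  stepwise mutation model (default μ = 0.002 per locus per meiosis), mixed
  with unrelated samples drawn from allele-frequency tables.

## Worked example

```python
>>> import ystr
>>> obrien = ystr.get_fixture_population("obrien")
>>> ystr.percent_similarity(obrien["OB8"], obrien["OB9"]).percent
12.5
```

OB8 and OB9 match at only 2 of 16 loci. Note OB9 carries a duplicated
{15,16} pattern at DYS437, which does *not* match OB8's single 15 — both
alleles of a multiset must agree.

```python
>>> est = ystr.haplotype_frequency(obrien["OB5"], obrien)
>>> est.X, est.N, ystr.format_one_in_n(est)
(2, 10, '1 in 5')
```

OB5's haplotype appears twice in the ten-sample database (OB6 is an
identical, coincidental match from the same county), so the counting
method gives 2/10.

```python
>>> sig = ystr.get_fixture_signature("dal_riata")
>>> ystr.classify_population(obrien, sig, ignore={"DYS389II"}).matching_sample_ids
('OB9', 'OB11')
```

Two of the ten surname samples are consistent with the six-locus Dal Riata
founder signature once its anomalous DYS389II value is set aside.

The same analyses are available from the shell; every subcommand accepts
`--in FILE` or a packaged population via `--fixtures`:

```console
$ ystr --quiet freq --fixtures obrien --sample OB5
{"sample": "OB5", "X": 2, "N": 10, "frequency": 0.2, "one_in_n": "1 in 5"}
$ ystr --quiet classify --fixtures control --signature dal_riata --ignore DYS389II
{"signature": "dal_riata", "ignored_loci": ["DYS389II"], "matches": ["C6", "C7"], "match_count": 2}
```

Subcommands: `convert`, `similarity`, `matrix`, `classes`, `freq`,
`sharing`, `classify`, `simulate`. See `docs/methods.md` for the model and
its assumptions.

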