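# partax

Partial-area taxonomy derivation and small partial-area quality assurance
for biomedical ontologies.

## The problem

Large biomedical ontologies (SNOMED CT, NCIt, and hundreds more) contain
modelling errors that human curators cannot find by exhaustive review.
One proven strategy is to audit where errors concentrate.  A *partial-area
taxonomy* is a summarization network of a concept hierarchy: concepts are
grouped into **areas** — maximal sets sharing exactly the same set of
lateral (non-hierarchical) relationship types — and each area is divided
into **partial-areas**, one per area root, containing the root plus every
area member reachable from it by an is-a path inside the area.  Concepts
in *small* partial-areas (size ≤ a bound *b*) carry rare combinations of
structure and semantics: they are outlier, uncommonly modelled concepts,
and they harbour errors at a significantly higher rate than concepts in
large partial-areas.  Auditing them first yields more corrections per
reviewed concept.

`partax` is for ontology curators and QA researchers.  It implements:

- loading a hierarchy as three TSV tables (concepts, is-a edges, lateral
  assertions) or an OBO file, with DAG validation and relationship-type
  inheritance (`partax.ontology`);
- derivation of area and partial-area taxonomies, overlapping-concept
  detection, size distributions, and subtaxonomies restricted to a subset
  of relationship types (`partax.taxonomy`);
- the blinded, stratified audit-sampling study design and its analysis:
  sampling frames that exclude overlapping concepts, proportional or
  fixed per-size allocation, seeded blinded draws, per-size error tables,
  threshold selection, and the two-tailed Fisher exact test on the
  2×2 erroneous × small/large contingency (`partax.audit`);
- family-level applicability statistics: exact (Clopper–Pearson) central
  binomial confidence intervals and the minimum-study rule — 6/6, 8/9,
  10/12 successes place the 95% CI lower bound above 0.5, so the
  technique applies to at least half of a structural family of
  ontologies (`partax.family`);
- seeded synthetic ontologies with planted stratum-specific error rates
  and a simulated auditor, for testing and power analysis
  (`partax.simulate`).

## The statistics

For an audit of *n*ₛ concepts from small and *n*ₗ from large
partial-areas with *a* and *c* erroneous respectively, the hypothesis
"small partial-areas harbour more errors" is tested on the table
(*a*, *n*ₛ−*a*; *c*, *n*ₗ−*c*) with the two-tailed Fisher exact test
(point-probability convention: the p-value sums the probabilities of all
tables with the observed margins whose hypergeometric point probability
does not exceed that of the observed table).  The bound *b** is chosen
from candidates 1..10 to minimise p.  Treating each per-ontology study as
a Bernoulli trial, *i* successes in *n* studies give the exact central
95% CI with endpoints from the Beta(i, n−i+1) / Beta(i+1, n−i) quantiles;
the technique is declared family-applicable when the lower bound exceeds
0.5.

## Worked example

The package ships the per-size audit outcomes of two hierarchy-scale
review studies as reference datasets.  Analysing the SNOMED CT *Specimen*
audit (100 concepts reviewed, 14 erroneous):

```python
import partax as px
from partax.datasets import specimen_size_error_table

table = specimen_size_error_table()
scan = px.select_threshold(table)
ct = px.contingency_at_threshold(table, scan.b_star)
print("selected threshold b* =", scan.b_star)
print("contingency (a, b, c, d) =", (ct.a, ct.b, ct.c, ct.d))
print(f"error rates: small {100*ct.small_error_rate:.1f}%, large {100*ct.large_error_rate:.1f}%")
print(f"two-tailed Fisher exact p = {px.fisher_exact_two_tailed(ct):.4f}")
d = px.family_applicability(6, 6)
print(f"6/6 studies: 95% CI [{d.ci.lower:.3f}, {d.ci.upper:.3f}] -> applicable: {d.applicable}")
```

prints

```
selected threshold b* = 9
contingency (a, b, c, d) = (11, 38, 3, 48)
error rates: small 22.4%, large 5.9%
two-tailed Fisher exact p = 0.0215
6/6 studies: 95% CI [0.541, 1.000] -> applicable: True
```

The scan selects size 9 as the small/large bound; of 49 sampled
small-partial-area concepts 11 were erroneous (22.4%) against 3 of 51
(5.9%) from large partial-areas, a significant difference (p < 0.05).
The 6-of-6 line shows why six successful studies suffice to claim a QA
technique for a whole ontology family: the exact CI on the per-ontology
success probability excludes 0.5.

The same pipeline runs from the shell.  `partax fixture` writes a
12-concept example hierarchy; deriving its taxonomy:

```
$ partax fixture --out fx
$ partax derive --concepts fx/concepts.tsv --isa fx/isa.tsv --lateral fx/lateral.tsv --out tax
12 concepts, 4 areas, 5 partial-areas, 0 overlapping
```

`partax sample` draws a blinded audit worksheet (`--seed` required),
`partax analyze` turns reviewer results into the full report, `partax
simulate` generates a complete synthetic study, and `partax family-ci` /
`family-min-n` / `classify` cover the family-applicability side.

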