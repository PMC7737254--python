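# Methods

## Summarization model

An ontology hierarchy is a rooted DAG of concepts under is-a
(subsumption), where each concept carries a set of lateral
relationship-type names (SNOMED CT attribute relationships, NCIt roles).
Lateral targets are opaque: they may lie in other hierarchies and are
never validated against the loaded concept set, since only the *type*
set matters for summarization.

Two derivation modes control the effective type set.  `asserted` (the
default) takes the input sets as-is, which is correct for inferred
(reasoner-materialised) releases where inheritance is already explicit.
`inherited` unions each concept's set with those of all its ancestors,
for raw stated inputs, reflecting that lateral relationships are
inherited down the is-a hierarchy.  On inputs whose sets already respect
inheritance the two modes coincide (a property the synthetic generator
maintains and the tests exercise).

**Areas** partition the concept set by exact equality of effective type
sets (no subset/superset merging).  An area **root** is a member all of
whose parents lie outside the area; the **partial-area** of a root r
contains r plus every area member reachable from r by an is-a path lying
entirely inside the area.  We chose path-containment over the looser
"any descendant in the same area" reading because it matches the
root/child-of semantics of the summarization network: every partial-area
member is connected to its root within the area.  The looser reading is
available as `membership='descendant'`.  Child-of links are induced by
roots' parents (node A is child-of B when A's root has a parent in B)
and are acyclic by construction, which the tests check against
brute-force oracles on random DAGs.

A concept belonging to two or more partial-areas is **overlapping**;
this requires multiple parents.  Overlapping concepts are themselves
error-prone, so audit sampling frames exclude them by default to avoid
confounding the small-vs-large comparison.

**Subtaxonomies** restrict every concept's type set to a chosen subset
before derivation, coarsening the summary; with the full type set the
derivation is unchanged (tested as an identity).

## Audit study design

The frame annotates each eligible (non-overlapping) concept with its
partial-area size and a stratum: the size itself up to an initial bound
(default 10), else a single large stratum.  If exclusion is switched
off, an overlapping concept is assigned the smallest size among its
partial-areas, biasing toward the small side; this path is off the
standard design.  Two allocation designs are provided, matching the two
reference studies:

- **proportional**: a small-side quota (50 by default) split across
  sizes 1..bound proportionally to eligible population, rounded by
  largest remainder (Hamilton) so quotas sum exactly and each differs
  from its exact share by less than one;
- **fixed per size**: explicit quotas such as 10 at size 1 and 5 at each
  of sizes 2..10; an underpopulated stratum contributes everything it
  has, with a warning, and an empty stratum is skipped.

Draws are uniform without replacement within strata, then shuffled
together; the exported worksheet carries only order, concept id and
label, so the reviewer is blind to both the hypothesis and the strata.
Every stochastic step takes an explicit seed; there is no hidden global
randomness.

Analysis collapses the per-size error table at each candidate bound into
a 2×2 erroneous × small/large contingency and applies the two-tailed
Fisher exact test under the point-probability convention (sum of
hypergeometric point probabilities not exceeding the observed one,
with a 1e-7 relative tolerance on the comparison — the convention of R's
`fisher.test`, delegated to `scipy.stats.fisher_exact` and verified
against an exact-fraction enumeration oracle for all margins up to 12).
The selected bound b\* minimises p over the candidates (default 1..10);
ties break toward the smaller bound, the stronger "small" claim.  The
hypothesis is reported as supported at b\* when p < 0.05 (two-sided),
the fixed significance criterion throughout.

Selecting b\* by minimum p is an exploratory step; the per-candidate
scan is always retained so a reader can see the sensitivity (e.g. the
specimen audit is significant at both bounds 9 and 10).  The power
experiment therefore tests at a *fixed* planted bound, keeping the null
calibration exact.

## Family applicability

Each per-ontology study is a Bernoulli trial; i successes in n studies
give the exact central Clopper–Pearson 95% CI via the standard beta
characterisation: lower endpoint the 0.025 quantile of Beta(i, n−i+1)
(0 when i = 0), upper the 0.975 quantile of Beta(i+1, n−i) (1 when
i = n).  Exact central intervals are used because family sizes are small
and conservatism is preferred over shorter asymmetric intervals.
Applicability to at least half of a family requires the lower bound to
*strictly* exceed 0.5; the smallest all-success design satisfying this
is n = 6, with one allowed failure n = 9, with two n = 12
(`min_studies_required`, checked exhaustively for consistency at n−1).

Structural families are keyed on two booleans: any lateral assertions
present (object properties — required for non-trivial partial-area
taxonomies) and any concept with multiple parents (DAG vs tree —
required for overlapping concepts).  Labels are the 2×2 grid tokens
`OP/noOP + DAG/tree`; a data-properties dimension is deliberately not
modelled, as it plays no role in these QA techniques.

## Synthetic data

The generator grows a rooted DAG by preferential attachment: concept i
attaches to an existing concept with weight 1 + its current child count,
and with probability `multi_parent_prob` (default 0.15) to a second,
uniformly chosen parent.  A child's type set starts as the union of its
parents' sets and gains one absent type with probability `mutation_prob`
(default 0.15) — mutations spawn new areas; inheritance keeps the graphs
consistent with an inferred release.  Defaults of 1500 concepts and 4
relationship types produce frames with several hundred concepts on each
side of bound 9, the shape of a specimen-hierarchy-scale study; the
error model defaults plant 22.4% (small) vs 5.9% (large) at bound 9,
the stratum rates of the specimen reference audit.  The simulated
auditor flags planted errors with configurable sensitivity (default 1.0)
and clean concepts with a false-positive rate (default 0.0).

What the generator does **not** emulate: real terminological content
(labels are synthetic tokens), the heavy-tailed partial-area size
distributions of production ontologies (thousands of singletons next to
one huge partial-area), error correlation within partial-areas, and
reviewer disagreement.  Passing tests on synthetic data therefore
demonstrate correctness of the derivation and the statistical machinery
and calibration of the design, not field performance on any particular
ontology.

The power experiment fixes one generated ontology and its frame, then
per replicate replants errors, redraws the stratified sample, simulates
the audit and tests at the planted bound; 500 replicates of the 50/50
design give roughly 55% power against the default planted rates and a
type-I error comfortably below 0.05 under equal rates (Fisher's exact
test is conservative).  These problem sizes keep the full suite and the
reproduction script fast while leaving Monte-Carlo error well inside the
asserted margins.

## Numerical choices and edge cases

- Concept ids are exact, case-sensitive strings; duplicate ids, unknown
  edge endpoints, self-edges and cycles are rejected at load time, with
  the offending cycle listed.
- Empty type sets are first-class (the Ø area); a hierarchy with no
  lateral assertions yields exactly one area.
- All derivation outputs are sorted (size descending, label ascending;
  link lists lexicographic) so repeated runs are byte-identical.
- Proportional allocation caps each per-size quota at its population and
  redistributes the remainder; an infeasible total quota is an error
  naming the stratum.
- The Fisher test rejects an all-zero table; a table with an empty
  margin returns p = 1 through the underlying implementation.
- Clopper–Pearson endpoints are computed to full double precision and
  displayed to three decimals in the CLI.

## Known limitations

- Partial-area membership under the `descendant` switch is provided for
  comparison but untested against published counts, which require
  licensed releases.
- The threshold scan reuses the same audit data that the final test
  evaluates; the reported p at b\* is not corrected for the selection.
  This mirrors the published design and is flagged above.
- The OBO reader maps only `is_a` and `relationship:` lines; OWL inputs
  and description-logic reasoning are out of scope — inputs are expected
  to be already-classified releases exported to tables.
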