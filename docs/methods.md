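# Methods

This note records the statistical procedures phenogpc implements, the
choices made where the design was genuinely open, and what the synthetic
validation studies do and do not demonstrate.

## Data model and propagation

An individual is the subset of a GA4GH v2 phenopacket the analysis needs:
sex, age at last encounter, vital status with optional age at death,
diseases with optional onset, phenotype observations (HPO term, observed
or excluded, optional onset), causal variants, and coded numeric
measurements. Ages are ISO-8601 periods normalized to days with
1 y = 365.25 d and 1 mo = 30.44 d. Absence of a term from a record means
*not assayed* — never excluded. Missing fields are dropped (with a warning
for unparseable onsets), never imputed. Validation rejects duplicate
individual ids and totals of causal alleles outside {1, 2}; multi-variant
genotypes beyond two causal alleles have no defined class under any
classifier, so they are refused at load rather than silently mis-binned.

Observed annotations propagate to all ancestors of the annotated term
(the true path rule). Excluded annotations propagate to all descendants:
excluding a general term logically excludes every specialization, and
without this rule the "excluded" column of the contingency tables would
undercount. The upward-observed and downward-excluded closures can meet
when source annotations disagree (e.g. a specific seizure type observed
while *Seizure* is excluded); such terms are flagged conflicting and
removed from that individual's analyzable set, consistent with the
general policy of omitting unusable data points rather than guessing.
Propagation is idempotent and monotone in observed annotations; both
properties are under test.

## Genotype classes

Variant predicates evaluate leaf conditions (effect category, exon
overlap, closed-interval protein-region overlap, variant key, structural
type, signed change length, reference length, structural deletion of at
least *n* bp) combined by AND/OR/NOT. A leaf whose attribute is absent
from a variant — a protein-region test against a variant with no protein
coordinates — evaluates to false rather than erroring, so predicates run
over mixed SNV/structural cohorts. Malformed trees fail at construction,
never at evaluation.

The monoallelic classifier assigns individuals with exactly one A-matching
allele (and no B) to class A and vice versa; anything else is omitted,
including alleles matching both predicates when A and B are supplied
non-exclusively (logged, since it usually indicates a mis-specified
hypothesis). Hemizygous variants count as one allele, so X-linked cohorts
mix hemizygous males and heterozygous females in the same class. The
biallelic classifier requires exactly two accounted alleles and partitions
the A-count {2, 1, 0} as AA/AB/BB or one of the two two-way merges; the
merges are coarsenings, so counts are conserved. Allele-count (1 vs 2),
sex (unknown omitted), and diagnosis (both/neither omitted) complete the
set. Classes plus the omitted set always partition the cohort.

## Independent filtering

Tested terms are chosen by five rules applied in a fixed order, each skip
attributed to the first matching rule, using only propagated counts and
the graph — never a p-value. Defaults: coverage threshold 0.4 of the
entire cohort (assayed = observed + excluded; an observed-only reading is
available by flag), minimum totals 7 for two classes and 6 for three,
and "general level" meaning the phenotypic-abnormality subroot plus its
direct children (the depth is configurable for analysts who want to skip
grandchildren as well). The parent-equals-child rule compares the full
count vector against every child that carries counts, whether or not that
child itself survives filtering — the parent's test would duplicate the
child's either way. Terms never annotated in the cohort are not
enumerated at all. The decisions are exported as a TSV ledger (term,
verdict, reason, per-class counts) so a reviewer can audit every skip.

Because the filter is independent of the test statistic under the null,
the downstream correction remains valid over the reduced family; the
acceptance suite checks the rejection rate empirically (below) and also
verifies mechanically that filtering runs with the Fisher-test machinery
disabled.

## Statistical tests

*Fisher exact.* Two-sided 2×2 p-values use the point-probability
criterion: the sum of hypergeometric probabilities of all same-margin
tables whose probability does not exceed the observed one, with a
1 + 1e-7 relative tolerance on the comparison to keep float-boundary
tables from flipping. k×2 tables use the Freeman–Halton extension,
computed by full enumeration of margin-preserving tables in log space
(cohort-scale margins keep the enumeration in the thousands of tables).
Degenerate tables (a zero row or column margin) return p = 1 by
convention. Both paths are tested against an exact rational-arithmetic
enumeration oracle to 1e-9 relative.

*Mann-Whitney U.* NaN scores are dropped; the exact null distribution is
used when both groups have at most 8 values and no ties, otherwise the
normal approximation with tie and continuity corrections. Verified
against full permutation enumeration in the exact regime.

*t-test.* Unpaired, two-sided, pooled-variance Student form by default
with a Welch flag; groups need at least two values each. The published
analyses this package mirrors do not state the variance treatment, so the
classical pooled form is the default and the choice is explicit in the
API.

*Logrank.* Standard chi-square with one degree of freedom over pooled
distinct event times, hypergeometric variance for ties (delegated to
lifelines, verified against hand-tabulated risk tables). Durations must
be positive; with no events in either group the test is reported as not
performed.

*Multiple testing.* Benjamini-Hochberg by default over exactly the tests
performed after filtering; Bonferroni, Šidák, Holm, Holm-Šidák, Hochberg,
Hommel, Benjamini-Yekutieli, two-stage BH, the two-stage
Benjamini-Krieger-Yekutieli procedure, and no correction are also
available. Score, measurement, and survival tests are treated as distinct
prior hypotheses and reported uncorrected, with the number of tests
performed alongside. Significance is p < 0.05 throughout.

## Severity scores

The counting scorer maps a stipulated set of organ-system terms to the
number of set members observed directly or through any descendant; each
member contributes at most one point regardless of how many descendants
are annotated.

The modified de Vries score is an operationalization of the published
rubric, expressed as HPO term sets and therefore fully configurable:
severe/profound intellectual disability 2 points or mild/moderate 1
(highest applicable only); any prenatal growth abnormality 2; postnatal
growth items (short stature, tall stature, microcephaly, macrocephaly) 1
each capped at 2; two or more *directly annotated* facial dysmorphism
terms 2 (propagated intermediates are not counted, which would otherwise
let a single deep annotation satisfy the pair requirement); non-facial
dysmorphism / congenital anomaly items 1 each capped at 2 — total range
0–10. Whether the original instrument caps categories exactly this way
cannot be settled from the sources available to this package; the rubric
is documented and overridable, and no validation claim is attached to the
default. An individual with no assayed term in any rubric category scores
NaN and is excluded from comparison, the same contract user-defined
scorers follow. Excluded annotations never subtract points.

## Survival endpoints

Events are derived per endpoint kind. Term onset: the minimum onset over
the endpoint term and its observed descendants (youngest-descendant
rollup); an observed relevant term *without* an onset age makes the
individual missing rather than an event at an unknown time — no
imputation. Death: event at age at death for deceased individuals,
censoring at last encounter otherwise (including unknown vital status).
Disease onset: event at the recorded onset; diagnosed individuals without
onset are missing. Individuals without the event and with a known age at
last encounter are right-censored there; an explicitly excluded endpoint
term also censors at last encounter, since exclusion is a statement about
the record so far, not a lifetime guarantee. Missing individuals are
excluded from the logrank test and tallied.

## Synthetic validation studies

The generator emulates the structure of curated rare-disease cohorts: a
toy ontology (rooted tree, optionally with diamond edges), two genotype
classes carrying heterozygous missense vs stop-gained variants, Bernoulli
observed/excluded annotations planted at leaf terms with configurable
assay coverage, exponential onset ages with right censoring, and normal
measurements. Internal-node counts arise only through propagation, which
exercises the parent-equals-child rule naturally. Each individual draws
from a stream keyed by (seed, index), so cohorts are byte-reproducible.

Study conditions (fixed in the package, reused by the acceptance script):

- **Null study** — 20 leaf terms at class-equal frequencies 0.4–0.6,
  50 individuals per class, 1000 replicates. Reported: the raw Fisher
  rejection rate at α = 0.05 over the leaf-term hypotheses (the discrete
  test is conservative, so ~0.035 rather than 0.05 is expected), and the
  fraction of replicates where the full filter + BH pipeline reports zero
  significant terms.
- **Planted frequency effect** — one leaf at 0.8 vs 0.2 plus five
  no-effect leaves, 50 per class, 100 replicates; reported: the fraction
  of runs flagging the planted term after correction.
- **Planted hazard ratio** — exponential onsets at 0.6 vs 0.2 events per
  year (hazard ratio 3), 30 per class, 20% censoring, 200 replicates;
  reported: logrank power at p < 0.05.

These sizes mirror a mid-sized published cohort (~50 individuals per
class) and complete in well under a minute. What passing them shows: the
pipeline controls type-I error under the null and recovers effects of the
planted size at these sample sizes. What they do not show: performance on
real cohorts, whose annotations are sparser, correlated across organ
systems, curated from heterogeneous publications, and subject to
ascertainment bias — none of which the Bernoulli-at-leaves generator
models.

## Numerical and degenerate-input conventions

Fisher comparisons use the 1 + 1e-7 relative tolerance above; zero-margin
tables give p = 1; two zero-variance groups with equal means give
t = 0, p = 1; empty groups, groups below minimum size, and event-free
survival comparisons are reported as not performed with a reason string
rather than raising. Results are sorted by (adjusted p, raw p, term id)
so reports are byte-identical across runs. Ontology loading rejects
cycles (naming an offending edge) and edges to undeclared terms; alt-id
mappings resolve to primary ids; deprecated terms are dropped.

## Known limitations

Only `is_a` relations are used; non-is_a axes (part-of, modifiers) are out
of scope. Variant functional annotation must arrive in the input records —
there is no built-in transcript annotation service, and the lollipop plot
takes a user-supplied protein domain table rather than querying any API.
The lollipop plot omits variants without protein coordinates (structural
and non-coding variants) and reports the omission tally. Cox regression,
competing risks, and interval censoring are not implemented. The exact
k×2 enumeration is practical for the 2–3 classes the classifiers produce,
not for general r×c tables.
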