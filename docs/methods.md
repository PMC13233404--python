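# Methods

## The annotation model

A phenotype ontology is an acyclic `is_a` graph. We restrict attention to
the subtree under a configurable root (for the HPO, "Phenotypic
abnormality"); the root's direct children are the *branches*, and a term
belongs to every branch among its ancestors-or-self — in a multi-parent
DAG that can be more than one, and per-branch summaries count such terms
once in each containing branch. Depth is the shortest parent-path to the
root (root = 0); shortest-path is chosen over longest-path because it is
deterministic, cheap, and the convention in HPO level analyses. Obsolete
terms are parsed and retained with a flag but excluded from traversal,
truth sets and annotation: they cannot be annotated. OBO files are read
through `obonet`; obographs-JSON through a small internal reader that keeps
only `is_a`/`rdfs:subClassOf` edges. Both loaders agree exactly on shared
fixtures (tested).

Each phenotype is annotated with the frequency at which it **directly
causes** each of ten clinical characteristics, on the ordered vocabulary
never (0), rarely (1), often (2), always (3), with a justification per
answer. The direct-causation restriction matters: annotators (human or
LLM) otherwise drift into risk-factor reasoning ("obesity ... cancer").
Prompts carry at most two phenotypes — the limit at which structured LLM
responses stay reliable — and enumerate the characteristics, the
vocabulary, the justification requirement and the direct-causation
instruction. The response grammar is line-oriented
(`<id> | <name> | <characteristic>: <frequency> - <justification>`) with a
strict-JSON alternative; the mock annotator emits it and the parser
round-trips it exactly. The batch driver retries failed queries
(`max_retries`, default 2) and records permanent failures rather than
dropping them.

## Severity score

Frequency code times characteristic weight, summed and normalised:

    NSS_p = 100 · Σ_j W_j·F_pj / Σ_j W_j·F_max .

Default weights (1–6 scale, 6 most severe): death 6, intellectual
disability 5, impaired mobility 4, blindness 4, physical malformations,
sensory impairments, immunodeficiency, cancer 3 each, reduced fertility 1,
congenital onset 1. The denominator Σ W_j·F_max = 99 is the theoretical
maximum over all ten characteristics, so the all-always profile maps to
exactly 100 and all-never to 0, and NSS is (100/99) times an integer in
[0, 99]. NSS is monotone in every characteristic's frequency (property-
tested). Blindness keeps weight 4 (grouped with impaired mobility in the
published weight table) even though the tier map below places it in
tier 3; the two structures are deliberately separate.

## Severity class

Characteristics are ranked into tiers adapted from the Lazarin et al.
carrier-screening severity survey: death and intellectual disability tier
1; impaired mobility and physical malformations tier 2; blindness, sensory
impairments, immunodeficiency and cancer tier 3; reduced fertility tier 4.
Congenital onset has no tier: it contributes to the score (it appears in
the weight table) but never to the class — both maps are explicit so the
asymmetry is visible. With H the set of characteristics annotated
often/always:

- Profound: |H ∩ Tier1| ≥ 2
- Severe: |H ∩ Tier1| = 1, or |H ∩ (Tier2 ∪ Tier3)| ≥ 3
- Moderate: |H ∩ Tier2| ≥ 1
- Mild: otherwise

When several rules fire, the most severe class wins. Note Moderate
requires a Tier-2 hit specifically: two tier-3 characteristics alone
remain Mild.

Replicates are scored and classified independently; an optional consensus
mode (modal frequency per characteristic, ties resolved towards the more
severe) exists but is off by default. Rankings sort by NSS with ties broken
by term id for determinism.

## Evaluation metrics

**Consistency** is computed per characteristic over phenotypes with ≥ 2
replicates. Lenient: all replicates fall in one of the groups
{always, often} or {never, rarely}. Stringent: all identical. With more
than two replicates we require *all* to agree — the strictest reading;
pairwise definitions only ever compare two. Chance levels for k uniform
replicates are exact: 2·(1/2)^k lenient, 4·(1/4)^k stringent (1/2 and 1/4
for pairs); Monte-Carlo rates under the bundled uniform-random annotator
converge to these (tested at n = 10,000 within 3 standard errors).

**Recall** (true positive rate): truth sets are the descendants-or-self of
terms matched by per-characteristic name queries (e.g. "Decreased
fertility", "Hypogonadism" for reduced fertility; the substring
"malformation" for physical malformations), minus exclusion substrings —
for blindness, colour and night blindness, which are not complete
blindness. Full term names match exactly; lower-case fragments match as
substrings; every query carries an explicit mode rather than a guessed
one. A truth member counts as a hit iff its annotation is often/always.
The denominator is truth members *present in the annotation set* (first
replicate by default, consensus optionally); empty denominators yield a
missing value, never 0. Congenital onset has no ontology-derived truth
set.

**Indirect-causation audit**: plain case-insensitive substring matching of
justifications against configurable patterns (defaults "indirectly",
"does not directly"); no stemming. Flagged (phenotype, characteristic)
cells can be reassigned to "never", which is provably score- and
class-monotone (frequencies only move down); both monotonicities are
property-tested.

**Associations**: Pearson correlations are computed on the numeric
frequency codes plus NSS; zero-variance columns give missing entries, not
0. Depth–consistency association reports (a) Spearman's rho between a
duplicated phenotype's depth and its fraction of stringently consistent
characteristics, and (b) Pearson chi-square (no continuity correction,
matching the closed-form Cramér's V = sqrt(χ²/(n·(min(r,c)−1)))) on the
depth-level × all-consistent table. The exact variable the original
depth analysis paired with Spearman's test is ambiguous, so the
implementation exposes the depth-vs-consistency reading and documents the
choice. Class/score concordance is a one-way between-groups partial
omega-squared of NSS across classes, ω²ₚ = (SSb − dfb·MSw)/(SSt + MSw),
with the F-test p-value; raw p-values throughout, no multiple-testing
correction.

## Synthetic data generator

The generator produces what the evaluation pipeline assumes about real
data: a rooted DAG whose branch roots carry the standard truth-set query
names (so benchmark truth sets are non-empty), four-level categorical
frequency marginals per characteristic, a duplicated subset with
independent replicate draws, justification text that is pattern-matchable,
and optional planted truth. Defaults mirror the published annotation
study's conditions: stylised marginals in which "never" dominates most
characteristics (e.g. death (0.45, 0.35, 0.19, 0.01) over
never/rarely/often/always, under 1% always-lethal) while congenital onset
is the exception (only ~22% never, matching the observation that rare
disorders are mostly congenital); 4.5% of phenotypes duplicated with 2
replicates (793 of 17,502 in the study); an indirect-phrase injection rate
of 2.6% of cells (4,495 flagged terms of 17,502 × 10 annotations).

Truth planting answers truth-set members often/always with probability
1 − ε and never/rarely otherwise, so measured recall estimates 1 − ε.
Cross-characteristic correlation is induced, when requested, by a Gaussian
copula: a shared standard-normal latent severity per phenotype mixed into
each characteristic's latent draw with weight sqrt(latent_r), then mapped
through the marginal's thresholds — marginals are preserved exactly while
characteristics correlate positively, which is what exercises the
correlation and concordance analyses non-trivially.

What the generator does **not** emulate: real HPO term names beyond
query-matching stubs, semantic coherence between a phenotype's
characteristics (beyond the latent factor), realistic justification prose,
annotator biases that correlate with ontology depth, or the HPO's actual
branch-size distribution. Passing tests therefore demonstrate that the
metrics and scores are computed correctly and recover planted structure —
not that any particular annotator is accurate on real data.

## Numerical and interface choices

- Frequencies are stored lower-case in CSV and read case-insensitively;
  columns are in the canonical characteristic order and rows sorted by
  (term id, replicate), so files are byte-stable and diff-friendly.
  Quoting follows RFC 4180.
- All randomised procedures take an explicit integer seed; the mock
  annotator is a pure hash of (seed, term, characteristic) so repeated
  calls are byte-identical, while the uniform-random annotator is
  deliberately stateful (fresh draws per call) for null experiments.
- Degenerate inputs raise informative errors rather than returning
  defaults: no duplicated phenotypes (consistency), a single depth level
  or single populated class (associations), < 3 records (correlations),
  cycles or unresolvable roots (loading).
- Problem sizes in the test suite: Monte-Carlo consistency uses ~10,000
  duplicated phenotypes; recall recovery uses ≥ 200 truth members per
  characteristic at ε ∈ {0, 0.1, 0.25}; the end-to-end scale test runs
  the full simulate → score → classify pipeline at 17,500+ terms, the real
  HPO's order of magnitude.

## Known limitations

- The published annotation resource (17,502 GPT-4-annotated HPO terms) and
  its headline rates are not reproducible offline; this package provides
  the machinery, formula-level reproductions and planted-truth recoveries
  instead.
- Truth-set sizes depend on the ontology release and query modes; the
  default benchmark is a faithful encoding of the standard queries, not a
  guarantee of any particular member count.
- Only `is_a` edges are traversed; `part_of` and other relations are out
  of scope, as is ontology editing.
- A live LLM adapter is intentionally out of the tested surface; anything
  satisfying the `prompt -> response` callable contract plugs in.
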