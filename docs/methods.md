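# Methods

## Model

An entity (gene, genotype, strain, QTL, disease, drug) is its set of
annotated phenotype classes, treated conjunctively. All reasoning
happens on the superclass closure `Cl(X) = X ∪ {ancestors of X}` under
the `is_a` relation of one canonical ontology. Two modelling choices
follow from this:

* **Information content is entity-level.** `P(X = C)` is the fraction of
  entities whose *closed* profile contains `C`, not a raw
  annotation-row frequency. Under closure this makes `I = -log P`
  well-defined and automatically monotone (a class can never be rarer
  than its subclass), which is the property the groupwise similarity
  ratio relies on. Raw-annotation counting is available as
  `compute_ic(..., counting="annotation")` for comparison only.
* **One canonical namespace.** Foreign-ontology query terms (e.g. human
  phenotype classes against a rodent corpus) are translated through a
  mapping table *before* closure; multi-target mappings contribute their
  whole target set (alignment tables derived from subclass reasoning are
  one-to-many by construction). The cross-species alignment itself is an
  input, not something this package computes.

simGIC is then `Σ I over Cl(P) ∩ Cl(R)` divided by `Σ I over
Cl(P) ∪ Cl(R)`.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| log base | natural log | simGIC is provably base-invariant (the base cancels in the ratio); the base only scales reported raw IC values and is recorded in the table. |
| unseen-term IC | `log(n_entities + 1)` | `I` is undefined at `P = 0`, but queries may legitimately use classes no corpus entity has; the pseudo-count cap makes them maximally informative yet finite. |
| unknown-term policy | warn-and-skip | user-facing search must tolerate stale ids (alt_id drift); `--strict` aborts instead. `replaced_by` following exists but is off by default. |
| edge relations | `is_a` only | phenotype ontologies are predominantly subclass hierarchies and the model is defined over subclass closure; other named relations can be opted in via `extra_relations`. |
| tie-breaking | ascending entity id | guarantees byte-identical output files across runs. |
| IC denominator | whole loaded corpus | strains, genes and QTLs are distinct entities and all enter the denominator; per-type restriction happens at search time, not in the IC table. |

Degenerate cases: `closure({}) = {}` (keeps extensivity/monotonicity
laws clean; empty queries are rejected upstream with a dedicated
error); a zero-IC union returns similarity 0, not NaN — a query carrying
no information should match nothing, itself included.

## Numerical determinism

Scores are accumulated in a single pass over the *sorted* union of the
two closures. Because IEEE addition of non-negative terms is monotone,
this makes the intersection sum never exceed the union sum, so the
[0, 1] bounds and `sim(P, P) = 1` hold exactly rather than to rounding;
it also makes the engine and the naive reference produce bit-identical
scores, so rank order (including ties) is reproducible.

## Search engine

The corpus is indexed by a per-term inverted index over closed
profiles. A query touches only the posting lists of its closed terms;
entities sharing no informative term sit in the zero-intersection case
of the formula and receive 0 without being scored. The equivalence of
this shortcut to exhaustive scoring is enforced by tests against
`oracle_search`, a deliberately naive reference that recomputes closures
and the whole IC table from scratch per call and evaluates the ratio by
direct set arithmetic.

## Evaluation

Candidate-gene prioritization scores all genes against each disease
profile and pools the labelled pairs across diseases into one ROC curve
(micro-averaging) — a single curve per evaluation set, which is what a
pooled sweep reproduces; a per-disease rank table (tie groups share mean
ranks, with a per-disease median) is emitted alongside. Negatives are
all non-associated pairs; nothing is sampled. Tied scores form one
threshold group (a diagonal segment), making the trapezoidal AUC equal
to the tie-corrected Mann–Whitney `U/(n_pos·n_neg)` — that closed form
is the module's exact test oracle. The curve itself comes from
scikit-learn's threshold sweep with no intermediate-point dropping.

## Synthetic data

The generators exist so that every pipeline stage is testable without
database downloads. `random_ontology` lays terms out in a topological
order and draws 1–3 parents per non-root term from earlier terms, so
acyclicity holds by construction rather than by rejection.
`random_corpus` samples uniform profiles (1–5 terms by default) from
non-root terms, keeping IC tables non-degenerate. `random_queries`
defaults to 1,000 queries of 10 distinct terms — the shape of the
real-time query-performance experiment this package's benchmark command
reproduces. The protocol runs against a 500-term / 2,000-entity
synthetic knowledge base, a size chosen so the whole end-to-end check
completes comfortably on a single CPU while still exercising the
inverted index; no wall-clock value is asserted anywhere because timing
is hardware-dependent.

What the generators do **not** emulate: the heavy-tailed term-frequency
distribution of real annotation corpora, annotation depth bias toward
well-studied genes, and correlated (co-annotated) phenotype modules.
Passing tests therefore demonstrate algorithmic correctness and
determinism, not retrieval quality on real databases — absolute AUCs on
real gene–disease sets depend on annotation practice (e.g. sparsely
annotated gene families can dominate the negatives) and on the quality
of the cross-ontology mapping supplied.

## Known limitations

* Only `is_a` closure by default; ontologies that encode meaningful
  phenotype structure in `part_of` need the relation opt-in.
* The mapping table is trusted as given; no reasoning over it.
* IC uses one global denominator over the loaded corpus; per-source IC
  (if a deployment mixes very differently-sized sources) is not
  implemented.
* `evaluate` ranks one entity type at a time (default `gene`).
* Alternative similarity measures (Resnik-style pairwise maxima,
  best-match averages) are out of scope.
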