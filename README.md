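# phenosearch

Phenotype-profile similarity search over ontology-annotated corpora, with
a candidate-gene prioritization evaluation.

## What problem this solves

Model-organism databases annotate genes, genotypes, strains and QTLs with
classes from phenotype ontologies (e.g. the Mammalian Phenotype Ontology,
MP); diseases and drugs carry comparable phenotype or side-effect
profiles. Given a user-specified set of phenotype terms — "which
genotypes, diseases or drugs look most like *this* phenotype profile?" —
`phenosearch` ranks every entity in such a knowledge base by a groupwise
semantic similarity, in real time and reproducibly. It is aimed at
computational phenomics: phenotype-driven candidate-gene prioritization,
cross-species phenotype matching, and drug-effect profile search.

## The model

Each entity is represented by the conjunction of its annotated classes.
Profiles are compared on their **superclass closure**: `Cl(X)` is `X`
plus every ancestor of a member of `X` under the subclass (`is_a`)
relation. The **information content** of a class `C` is

    I(C) = -log P(X = C)

with `P(X = C)` the fraction of corpus entities whose closed profile
contains `C` (rarer classes are more informative; the root scores 0).
Two closed profiles `P` and `R` are compared with **simGIC**, the
IC-weighted Jaccard index:

    sim(P, R) = Σ_{x ∈ Cl(P) ∩ Cl(R)} I(x)  /  Σ_{y ∈ Cl(P) ∪ Cl(R)} I(y)

`sim` is symmetric, lies in [0, 1], and is invariant to the log base of
`I`. Similarity is always computed inside one canonical ontology;
query terms from a foreign ontology (e.g. human phenotype classes
against a rodent corpus) are first translated through a mapping table.

Rankings are evaluated with a pooled ROC curve: every gene is scored
against each disease's phenotype profile, pairs are labelled by curated
associations, and the trapezoidal AUC (equal to the tie-corrected
Mann–Whitney statistic `U / (n_pos · n_neg)`) summarizes how well true
disease genes rise to the top.

## Worked example

The bundled synthetic fixture has five terms (`root`, `A`, `B`, `C⊑A`,
`D⊑A,B`) and four entities annotated as `e1:{C}`, `e2:{C,B}`, `e3:{D}`,
`e4:{B}`:

```bash
python -c "
from phenosearch import canonical_fixture, write_obo, write_annotations
g, c = canonical_fixture()
write_obo(g, 'fixture.obo'); write_annotations(c, 'annotations.tsv')"
phenosearch build --obo fixture.obo --annotations annotations.tsv \
    --out fixture.bundle.json
phenosearch query --bundle fixture.bundle.json --terms XP:0000003
```

prints

```
rank	entity_id	entity_type	species	score
1	e1	gene	synthetic	1.000000
2	e2	gene	synthetic	0.773213
3	e3	gene	synthetic	0.108363
4	e4	gene	synthetic	0.000000
```

Reading the numbers: the query `{C}` closes to `{C, A, root}`, which is
exactly `e1`'s closed profile, so `e1` scores 1. With four entities the
membership counts give `I(C) = ln 2`, `I(A) = I(B) = ln(4/3)`,
`I(root) = 0`, so for `e2` (closure `{C, A, B, root}`) the ratio is
`(ln 2 + ln 4/3) / (ln 2 + 2·ln 4/3) ≈ 0.773213`. `e4` shares only the
zero-IC root with the query and scores 0. The same arithmetic by hand
gives `sim(e3, e4) = ln(4/3) / (2·ln 2 + 2·ln 4/3) ≈ 0.146652`.

Other commands: `phenosearch evaluate` (pooled ROC/AUC plus a
per-disease rank table from disease profiles and curated associations)
and `phenosearch benchmark` (the 1,000 × 10-term random-query protocol
with wall-clock statistics and a seed-stable result checksum). Every
flag can be supplied via a YAML `--config` file; diagnostics go to
stderr, results to stdout.

### Converting real database dumps

Native loaders for MGI/RGD/SIDER/Orphanet dumps are out of scope; any
such source is used by converting it to the generic annotation TSV
(`entity_id  entity_type  species  term_id`, one row per annotation,
`#` comments ignored), the association TSV
(`disease_id  entity_id[  ortholog_of]`), and the mapping TSV
(`source_term  target_term`).

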