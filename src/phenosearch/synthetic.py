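"""Synthetic ontologies, corpora and queries, plus the naive reference search.

Every other module is testable without downloads through this one.  Two
kinds of fixture exist:

* the *canonical* 5-term / 4-entity fixture, whose similarity values can
  be evaluated by hand and anchor the worked examples;
* seeded random generators (ontology, corpus, query set) whose defaults
  mirror the query-performance experiment this package reproduces: 1,000
  random queries of 10 terms each.

Random ontologies are acyclic by construction: terms are laid out in a
random topological order and every non-root term draws its parents from
strictly earlier terms.  Root terms are excluded from annotation and
query sampling so generated IC tables are non-degenerate.

``oracle_search`` is the deliberately naive reference implementation of
the whole pipeline — closures and IC recomputed from scratch per call,
direct set arithmetic, no inverted index — against which the production
engine is equivalence-tested.

The generators emit the same OBO/TSV dialects the loaders consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import Corpus, EntityProfile, ICTable, build_corpus
from .errors import CorpusFormatError, EmptyQueryError
from .ontology import OntologyGraph, Term
from .similarity import QueryProfile, RankedResult

TERM_PREFIX = "XP"  # synthetic phenotype namespace
FOREIGN_PREFIX = "YP"  # synthetic foreign (query-side) namespace


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study instance.

    Defaults for the query block follow the real-time query experiment:
    1,000 random queries, 10 terms each.  All generation is deterministic
    given ``seed``.
    """

    n_terms: int = 50
    max_parents: int = 3
    n_entities: int = 100
    profile_size_range: tuple = (1, 5)
    n_queries: int = 1000
    terms_per_query: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 1 or self.n_entities < 0 or self.n_queries < 0:
            raise ValueError("fixture counts must be non-negative (n_terms >= 1)")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        lo, hi = self.profile_size_range
        if not (1 <= lo <= hi):
            raise ValueError("profile_size_range must satisfy 1 <= min <= max")
        if self.terms_per_query > self.n_terms:
            raise ValueError("terms_per_query cannot exceed n_terms")


def _term_id(i: int, prefix: str = TERM_PREFIX) -> str:
    return f"{prefix}:{i:07d}"


# -- canonical worked-example fixture ---------------------------------

CANONICAL_TERMS = {
    "XP:0000000": "root",
    "XP:0000001": "A",
    "XP:0000002": "B",
    "XP:0000003": "C",
    "XP:0000004": "D",
}
CANONICAL_EDGES = [
    ("XP:0000001", "XP:0000000"),  # A is_a root
    ("XP:0000002", "XP:0000000"),  # B is_a root
    ("XP:0000003", "XP:0000001"),  # C is_a A
    ("XP:0000004", "XP:0000001"),  # D is_a A
    ("XP:0000004", "XP:0000002"),  # D is_a B
]
CANONICAL_ANNOTATIONS = {
    "e1": ["XP:0000003"],
    "e2": ["XP:0000003", "XP:0000002"],
    "e3": ["XP:0000004"],
    "e4": ["XP:0000002"],
}


def canonical_fixture() -> tuple[OntologyGraph, Corpus]:
    """The hand-checkable anchor: terms {root, A, B, C, D} with edges
    C⊑A, D⊑A, D⊑B, A⊑root, B⊑root, and entities e1:{C}, e2:{C,B},
    e3:{D}, e4:{B}."""
    parents: dict[str, set] = {t: set() for t in CANONICAL_TERMS}
    for child, parent in CANONICAL_EDGES:
        parents[child].add(parent)
    graph = OntologyGraph(
        {
            tid: Term(id=tid, name=name, parents=frozenset(parents[tid]))
            for tid, name in CANONICAL_TERMS.items()
        }
    )
    rows = [
        (eid, "gene", "synthetic", term)
        for eid, terms in CANONICAL_ANNOTATIONS.items()
        for term in terms
    ]
    return graph, build_corpus(rows, graph)


# -- random generators -------------------------------------------------


def random_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Random DAG of ``spec.n_terms`` terms; term 0 is the sole root and
    each later term draws 1..max_parents distinct parents uniformly from
    earlier terms."""
    rng = np.random.default_rng(spec.seed)
    terms: dict[str, Term] = {}
    ids = [_term_id(i) for i in range(spec.n_terms)]
    for i, tid in enumerate(ids):
        if i == 0:
            parents: frozenset = frozenset()
        else:
            k = int(rng.integers(1, min(spec.max_parents, i) + 1))
            chosen = rng.choice(i, size=k, replace=False)
            parents = frozenset(ids[int(j)] for j in chosen)
        terms[tid] = Term(id=tid, name=f"synthetic term {i}", parents=parents)
    return OntologyGraph(terms)


def random_corpus(spec: FixtureSpec, graph: OntologyGraph) -> Corpus:
    """Random corpus: each entity annotated with a uniform-random profile
    (size drawn from ``profile_size_range``) sampled without replacement
    from non-root terms."""
    rng = np.random.default_rng(spec.seed + 1)
    candidates = sorted(graph.active_terms() - graph.roots)
    lo, hi = spec.profile_size_range
    if hi > len(candidates):
        raise CorpusFormatError(
            f"profile_size_range max {hi} exceeds the {len(candidates)} "
            "annotatable (non-root) terms"
        )
    rows = []
    for i in range(spec.n_entities):
        eid = f"E{i:05d}"
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(candidates), size=size, replace=False)
        for j in chosen:
            rows.append((eid, "gene", "synthetic", candidates[int(j)]))
    return build_corpus(rows, graph)


def random_queries(spec: FixtureSpec, graph: OntologyGraph) -> list:
    """``spec.n_queries`` random queries of ``spec.terms_per_query``
    distinct non-root terms each, sampled uniformly; deterministic per
    seed."""
    rng = np.random.default_rng(spec.seed + 2)
    candidates = sorted(graph.active_terms() - graph.roots)
    if spec.terms_per_query > len(candidates):
        raise EmptyQueryError(
            f"terms_per_query {spec.terms_per_query} exceeds the "
            f"{len(candidates)} usable (non-root) terms"
        )
    queries = []
    for _ in range(spec.n_queries):
        chosen = rng.choice(len(candidates), size=spec.terms_per_query, replace=False)
        queries.append([candidates[int(j)] for j in chosen])
    return queries


# -- file writers (round-trip with the loaders) ------------------------


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize an ontology to OBO 1.2 flat format, deterministically
    (terms and tags sorted)."""
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\nontology: synthetic-phenotype\n")
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            handle.write(f"\n[Term]\nid: {term.id}\n")
            if term.name:
                handle.write(f"name: {term.name}\n")
            for alt in sorted(term.alt_ids):
                handle.write(f"alt_id: {alt}\n")
            for parent in sorted(term.parents):
                parent_name = graph.terms[parent].name
                suffix = f" ! {parent_name}" if parent_name else ""
                handle.write(f"is_a: {parent}{suffix}\n")
            if term.obsolete:
                handle.write("is_obsolete: true\n")
            for rep in term.replaced_by:
                handle.write(f"replaced_by: {rep}\n")


def write_annotations(corpus: Corpus, path) -> None:
    """Serialize a corpus to the annotation TSV dialect ``load_annotations``
    consumes (annotated terms only; closures are recomputed on load)."""
    with open(path, "w") as handle:
        handle.write("entity_id\tentity_type\tspecies\tterm_id\n")
        for eid in sorted(corpus.profiles):
            profile = corpus.profiles[eid]
            for term in sorted(profile.annotated_terms):
                handle.write(
                    f"{eid}\t{profile.entity_type}\t{profile.species}\t{term}\n"
                )


# -- naive reference implementation ------------------------------------


def oracle_search(
    query_terms: Sequence[str],
    corpus: Corpus,
    graph: OntologyGraph,
    entity_type: Optional[str] = None,
    species: Optional[str] = None,
    top_k: Optional[int] = None,
) -> RankedResult:
    """Reference ranking with no indexing or caching.

    Recomputes every closure and the whole IC table from scratch, then
    evaluates the intersection/union IC ratio against every entity by
    direct set arithmetic, with the same descending-score /
    ascending-entity-id tie rule as the engine.
    """
    # IC from scratch: entity-level closed-profile membership counts.
    closed_profiles = {
        eid: graph.closure(p.annotated_terms) for eid, p in corpus.profiles.items()
    }
    n = len(closed_profiles)
    if n == 0:
        raise CorpusFormatError("empty corpus")

    def ic(term: str) -> float:
        count = sum(1 for terms in closed_profiles.values() if term in terms)
        if count == 0:
            return math.log(n + 1)
        return -math.log(count / n)

    effective = []
    for t in query_terms:
        primary = graph.resolve(t)
        if primary not in effective:
            effective.append(primary)
    if not effective:
        raise EmptyQueryError("no usable query terms")
    query_closed = graph.closure(effective)

    entries = []
    for eid in corpus.profiles:
        profile = corpus.profiles[eid]
        if entity_type is not None and profile.entity_type != entity_type:
            continue
        if species is not None and profile.species != species:
            continue
        closed = closed_profiles[eid]
        # same sorted-union evaluation order as the engine, so that scores
        # are reproducible bit-for-bit and ties resolve identically
        inter = 0.0
        union = 0.0
        for t in sorted(query_closed | closed):
            weight = ic(t)
            union += weight
            if t in query_closed and t in closed:
                inter += weight
        score = inter / union if union > 0 else 0.0
        entries.append((eid, profile.entity_type, profile.species, score))
    entries.sort(key=lambda e: (-e[3], e[0]))
    if top_k is not None:
        entries = entries[:top_k]
    query = QueryProfile(
        raw_terms=tuple(query_terms),
        effective_terms=frozenset(effective),
        closed_terms=query_closed,
    )
    return RankedResult(entries=entries, query=query)
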