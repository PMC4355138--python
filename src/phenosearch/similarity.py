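"""simGIC similarity, cross-ontology query translation and corpus ranking.

simGIC is the information-content-weighted Jaccard index over superclass
closures: for closed profiles P and R,

    sim(P, R) = sum_{x in P ∩ R} I(x)  /  sum_{y in P ∪ R} I(y)

It is symmetric, bounded in [0, 1], equals 1 exactly when the two closures
agree on their positive-IC support, and is invariant to the log base of I.

Similarity is always computed in one canonical ontology namespace; query
terms from a foreign ontology (e.g. human phenotype classes against a
mouse/rat corpus) are first translated through a mapping table, then
closed in the canonical ontology.

Ranking the whole corpus uses a per-term inverted index over closed
profiles so that scoring touches only entities sharing at least one
closed term with the query; entities sharing none receive score 0 without
evaluation, which is exactly the zero-intersection case of the formula.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

import pandas as pd

from .corpus import Corpus, ICTable
from .errors import CorpusFormatError, EmptyQueryError, UnknownTermError
from .ontology import OntologyGraph, normalize_term_id

logger = logging.getLogger(__name__)


@dataclass
class MappingTable:
    """Foreign-term -> canonical-term translation pairs.

    Stands in for a reasoner-derived cross-ontology alignment; mappings
    may be one-to-many (subclass-based alignments are, by construction).
    All target ids must exist in the canonical ontology.
    """

    pairs: dict[str, frozenset]
    provenance: str = ""

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.pairs

    def targets(self, term_id: str) -> frozenset:
        return self.pairs.get(term_id, frozenset())


def load_mapping(path, graph: OntologyGraph, provenance: str = "") -> MappingTable:
    """Read a mapping TSV (columns source_term, target_term, one pair per
    row) and validate every target against the canonical ontology."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CorpusFormatError(f"mapping file {path!r} is empty") from exc
    for col in ("source_term", "target_term"):
        if col not in frame.columns:
            raise CorpusFormatError(f"mapping file {path!r} lacks column {col!r}")
    pairs: dict[str, set] = defaultdict(set)
    for source, target in frame[["source_term", "target_term"]].itertuples(
        index=False, name=None
    ):
        resolved = graph.resolve(target)  # raises UnknownTermError on bad target
        pairs[normalize_term_id(source)].add(resolved)
    return MappingTable(
        pairs={s: frozenset(t) for s, t in pairs.items()},
        provenance=provenance or str(path),
    )


@dataclass
class QueryProfile:
    """A user query: raw terms, their canonical effective set, its closure,
    and a record of anything skipped along the way."""

    raw_terms: tuple
    effective_terms: frozenset
    closed_terms: frozenset
    skipped_terms: tuple = ()


def translate_query(
    terms: Sequence[str],
    graph: OntologyGraph,
    mapping: Optional[MappingTable] = None,
    strict: bool = False,
) -> tuple[list, list]:
    """Map query terms into the canonical namespace.

    Terms resolvable in the canonical ontology pass through (alt_ids
    resolved); foreign terms are replaced by their mapped target set
    (union semantics for one-to-many rows).  Unmappable terms raise under
    ``strict``, otherwise they are recorded as ``(term, reason)`` pairs.

    Returns ``(effective_terms, skipped)`` with effective terms in
    first-seen order, deduplicated.
    """
    effective: list = []
    seen: set = set()
    skipped: list = []

    def _keep(term: str) -> None:
        if term not in seen:
            seen.add(term)
            effective.append(term)

    for raw in terms:
        try:
            canonical = normalize_term_id(raw)
        except UnknownTermError as exc:
            if strict:
                raise
            skipped.append((raw, "malformed identifier"))
            continue
        try:
            _keep(graph.resolve(canonical))
            continue
        except UnknownTermError:
            pass
        if mapping is not None and canonical in mapping:
            for target in sorted(mapping.targets(canonical)):
                _keep(target)
            continue
        if strict:
            raise UnknownTermError(
                canonical, f"query term {canonical} is neither canonical nor mapped"
            )
        skipped.append((canonical, "not in ontology or mapping"))

    if skipped:
        logger.warning(
            "skipped %d query term(s): %s",
            len(skipped),
            "; ".join(f"{t} ({r})" for t, r in skipped),
        )
    return effective, skipped


def build_query(
    terms: Sequence[str],
    graph: OntologyGraph,
    mapping: Optional[MappingTable] = None,
    strict: bool = False,
) -> QueryProfile:
    """Resolve, translate and close a raw term list into a QueryProfile.

    Closure happens after translation, in the canonical ontology only.
    Raises :class:`EmptyQueryError` when nothing usable remains.
    """
    effective, skipped = translate_query(terms, graph, mapping=mapping, strict=strict)
    if not effective:
        raise EmptyQueryError("no usable query terms after resolution/translation")
    return QueryProfile(
        raw_terms=tuple(terms),
        effective_terms=frozenset(effective),
        closed_terms=graph.closure(effective),
        skipped_terms=tuple(skipped),
    )


def simgic(p: frozenset, r: frozenset, ic: ICTable) -> float:
    """Information-content-weighted Jaccard similarity of two *closed*
    term sets.

    Returns ``sum IC(intersection) / sum IC(union)`` in [0, 1].  When the
    union carries zero total IC (both profiles consist solely of zero-IC
    terms) the query carries no information and the result is 0, with a
    logged warning.
    """
    p = frozenset(p)
    r = frozenset(r)
    # One pass over the sorted union keeps the arithmetic deterministic and
    # symmetric; monotone IEEE addition then guarantees inter <= union, so
    # the [0, 1] bounds hold exactly (identity gives exactly 1.0).
    inter = 0.0
    union = 0.0
    both = p & r
    for term in sorted(p | r):
        weight = ic[term]
        union += weight
        if term in both:
            inter += weight
    if union <= 0.0:
        logger.warning("simgic denominator is zero (no informative terms); returning 0")
        return 0.0
    return inter / union


@dataclass
class RankedResult:
    """Ordered (entity_id, entity_type, species, score) rows for a query.

    Scores are non-increasing; ties are broken by ascending entity id so
    output files are reproducible.
    """

    entries: list
    query: Optional[QueryProfile] = None

    def __len__(self) -> int:
        return len(self.entries)

    def entity_ids(self) -> list:
        return [e[0] for e in self.entries]

    def scores(self) -> list:
        return [e[3] for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.entries, columns=["entity_id", "entity_type", "species", "score"]
        )
        frame.insert(0, "rank", range(1, len(frame) + 1))
        return frame

    def write_tsv(self, stream: TextIO) -> None:
        stream.write("rank\tentity_id\tentity_type\tspecies\tscore\n")
        for rank, (eid, etype, species, score) in enumerate(self.entries, start=1):
            stream.write(f"{rank}\t{eid}\t{etype}\t{species}\t{score:.6f}\n")


class SearchIndex:
    """Inverted index over closed profiles for repeated corpus ranking.

    Build once per (corpus, IC table); each query then touches only the
    posting lists of its closed terms.  Terms with zero IC contribute
    nothing to either sum and are excluded from the postings.
    """

    def __init__(self, corpus: Corpus, ic: ICTable):
        self.corpus = corpus
        self.ic = ic
        self._postings: dict[str, list] = defaultdict(list)
        for profile in corpus:
            for term in profile.closed_terms:
                if ic[term] > 0.0:
                    self._postings[term].append(profile.entity_id)

    def search(
        self,
        query: QueryProfile,
        entity_type: Optional[str] = None,
        species: Optional[str] = None,
        top_k: Optional[int] = None,
    ) -> RankedResult:
        """Score every entity passing the filter against the query closure.

        Posting lists identify the candidates sharing at least one
        informative closed term; only those are scored (the remainder sit
        in the zero-intersection case of the formula and receive 0
        outright).  Deterministic: descending score, ascending entity id
        on ties, truncated to ``top_k`` when given.
        """
        if not query.effective_terms:
            raise EmptyQueryError("no usable query terms")
        candidates: set = set()
        for term in query.closed_terms:
            if self.ic[term] > 0.0:
                candidates.update(self._postings.get(term, ()))

        entries = []
        for profile in self.corpus:
            if entity_type is not None and profile.entity_type != entity_type:
                continue
            if species is not None and profile.species != species:
                continue
            if profile.entity_id in candidates:
                score = simgic(query.closed_terms, profile.closed_terms, self.ic)
            else:
                score = 0.0
            entries.append(
                (profile.entity_id, profile.entity_type, profile.species, score)
            )

        entries.sort(key=lambda e: (-e[3], e[0]))
        if top_k is not None:
            entries = entries[:top_k]
        return RankedResult(entries=entries, query=query)


def search(
    query: QueryProfile,
    corpus: Corpus,
    ic: ICTable,
    entity_type: Optional[str] = None,
    species: Optional[str] = None,
    top_k: Optional[int] = None,
) -> RankedResult:
    """One-shot corpus ranking; builds a :class:`SearchIndex` internally.

    Callers issuing many queries against the same corpus should build the
    index once and reuse it.
    """
    index = SearchIndex(corpus, ic)
    return index.search(query, entity_type=entity_type, species=species, top_k=top_k)
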