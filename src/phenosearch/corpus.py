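"""Annotation corpus: entity phenotype profiles and information content.

An entity (gene, genotype, strain, QTL, disease or drug) is represented
by the *conjunction* of its annotated phenotype classes; its searchable
profile is the superclass closure of that conjunction.  The information
content of a class C is

    I(C) = -log P(X = C)

where P(X = C) is the fraction of corpus entities whose closed profile
contains C — rarer classes are more informative.  By construction every
closed profile containing a class also contains all of its superclasses,
so I is monotone non-increasing toward the root and I(root) = 0 whenever
one root subsumes every annotated term.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import CorpusFormatError, UnknownTermError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("gene", "genotype", "strain", "qtl", "disease", "drug", "other")

_REQUIRED_COLUMNS = ("entity_id", "entity_type", "species", "term_id")


@dataclass(frozen=True)
class EntityProfile:
    """One entity plus its annotated terms and their superclass closure."""

    entity_id: str
    entity_type: str
    species: str
    annotated_terms: frozenset
    closed_terms: frozenset

    def __post_init__(self):
        if self.entity_type not in ENTITY_TYPES:
            object.__setattr__(self, "entity_type", "other")


@dataclass
class Corpus:
    """The searchable phenotype knowledge base: entity_id -> profile."""

    profiles: dict[str, EntityProfile]

    @property
    def n_entities(self) -> int:
        return len(self.profiles)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.profiles

    def __iter__(self):
        return iter(self.profiles.values())

    def filter(
        self,
        entity_type: Optional[str] = None,
        species: Optional[str] = None,
    ) -> "Corpus":
        """Sub-corpus restricted by entity type and/or species label."""
        kept = {
            eid: p
            for eid, p in self.profiles.items()
            if (entity_type is None or p.entity_type == entity_type)
            and (species is None or p.species == species)
        }
        return Corpus(kept)

    def type_counts(self) -> dict[str, int]:
        return dict(Counter(p.entity_type for p in self.profiles.values()))


def build_corpus(
    rows: Iterable[tuple[str, str, str, str]],
    graph: OntologyGraph,
    strict: bool = False,
) -> Corpus:
    """Assemble a :class:`Corpus` from (entity_id, entity_type, species,
    term_id) rows.

    Duplicate (entity, term) rows are deduplicated.  Unresolvable term ids
    raise under ``strict``; otherwise they are skipped with a logged count
    and entities left with no usable terms are dropped with a warning.
    """
    annotated: dict[str, set] = {}
    meta: dict[str, tuple[str, str]] = {}
    n_skipped = 0
    for entity_id, entity_type, species, term_id in rows:
        try:
            primary = graph.resolve(term_id)
        except UnknownTermError:
            if strict:
                raise
            n_skipped += 1
            continue
        annotated.setdefault(entity_id, set()).add(primary)
        meta.setdefault(entity_id, (str(entity_type), str(species)))

    if n_skipped:
        logger.warning("skipped %d annotation rows with unresolvable terms", n_skipped)

    profiles: dict[str, EntityProfile] = {}
    for entity_id, terms in annotated.items():
        if not terms:
            continue
        entity_type, species = meta[entity_id]
        profiles[entity_id] = EntityProfile(
            entity_id=entity_id,
            entity_type=entity_type,
            species=species,
            annotated_terms=frozenset(terms),
            closed_terms=graph.closure(terms),
        )
    return Corpus(profiles)


def load_annotations(path, graph: OntologyGraph, strict: bool = False) -> Corpus:
    """Load an annotation TSV (columns entity_id, entity_type, species,
    term_id; ``#`` comment lines ignored) into a :class:`Corpus`.

    Entities whose every term was skipped under the lenient policy are
    dropped with a logged warning.
    """
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CorpusFormatError(f"annotation file {path!r} is empty") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CorpusFormatError(
            f"annotation file {path!r} lacks required column(s): {', '.join(missing)}"
        )
    if frame.empty:
        raise CorpusFormatError(f"annotation file {path!r} has no data rows")

    all_entities = set(frame["entity_id"])
    corpus = build_corpus(
        frame[list(_REQUIRED_COLUMNS)].itertuples(index=False, name=None),
        graph,
        strict=strict,
    )
    dropped = all_entities - set(corpus.profiles)
    if dropped:
        logger.warning(
            "dropped %d entities with no resolvable annotations: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    logger.info(
        "loaded corpus: %d entities (%s)",
        corpus.n_entities,
        ", ".join(f"{k}={v}" for k, v in sorted(corpus.type_counts().items())),
    )
    return corpus


@dataclass
class ICTable:
    """Per-term information content in units of ``log_base``.

    Terms absent from every closed profile receive the pseudo-count cap
    ``-log(1/(n_entities+1))``: the most informative finite value, so a
    query may legitimately use classes no corpus entity has.  simGIC is
    invariant to the log base (it cancels in the ratio), so the base only
    affects reported raw IC values.
    """

    values: dict[str, float]
    n_entities: int
    log_base: float = math.e

    def __getitem__(self, term_id: str) -> float:
        return self.values.get(term_id, self.unseen_ic)

    @property
    def unseen_ic(self) -> float:
        return math.log(self.n_entities + 1) / math.log(self.log_base)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.values

    def with_base(self, base: float) -> "ICTable":
        """Same table re-expressed in a different log base (> 1)."""
        if base <= 1:
            raise ValueError("log base must be > 1")
        factor = math.log(self.log_base) / math.log(base)
        return ICTable(
            values={t: v * factor for t, v in self.values.items()},
            n_entities=self.n_entities,
            log_base=base,
        )


def compute_ic(
    corpus: Corpus,
    graph: Optional[OntologyGraph] = None,
    counting: str = "entity",
) -> ICTable:
    """Compute the IC table from corpus annotation frequencies.

    ``counting="entity"`` (default): P(X=C) is the fraction of entities
    whose *closed* profile contains C — the unit that makes IC well-defined
    under closure and matches its groupwise use in the similarity ratio.
    ``counting="annotation"`` counts raw annotated-term occurrences
    (each deduplicated (entity, term) annotation, closed individually)
    and is provided for comparison only.
    """
    if corpus.n_entities == 0:
        raise CorpusFormatError("cannot compute information content of an empty corpus")
    counts: Counter = Counter()
    if counting == "entity":
        denominator = corpus.n_entities
        for profile in corpus:
            counts.update(profile.closed_terms)
    elif counting == "annotation":
        if graph is None:
            raise ValueError("annotation-level counting requires the ontology graph")
        denominator = sum(len(p.annotated_terms) for p in corpus)
        for profile in corpus:
            for term in profile.annotated_terms:
                counts.update(graph.closure([term]))
    else:
        raise ValueError(f"unknown counting mode: {counting!r}")

    # "+ 0.0" folds IEEE -0.0 (from -log(1)) into plain 0.0
    values = {
        term: -math.log(count / denominator) + 0.0 for term, count in counts.items()
    }
    return ICTable(values=values, n_entities=corpus.n_entities)
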