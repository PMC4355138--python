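"""Phenotype-ontology subclass graph with ancestor and closure queries.

The similarity machinery in this package operates on the *superclass
closure* of term sets: ``Cl(X)`` is the smallest superset of ``X`` closed
against the subclass (``is_a``) relation, i.e. ``X`` together with every
strict superclass of a member of ``X``.  This module parses an OBO 1.2
flat file into a validated directed acyclic graph and provides the
``ancestors`` / ``closure`` primitives everything else builds on.

Only ``is_a`` edges participate by default — phenotype ontologies such as
MP are predominantly ``is_a`` hierarchies and the similarity model is
defined over subclass closure.  Additional named relations (``part_of``,
...) can be opted in via ``extra_relations``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping

import networkx as nx
import obonet

from .errors import OboParseError, OntologyValidationError, UnknownTermError

logger = logging.getLogger(__name__)

# PREFIX:digits, e.g. "MP:0002657"; prefix is normalized to uppercase.
_TERM_ID_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*):(\d+)$")


def normalize_term_id(value: str) -> str:
    """Validate and normalize a term identifier to uppercase-prefix form.

    Raises :class:`UnknownTermError` when the string does not match the
    ``PREFIX:digits`` pattern at all (such a string can never resolve).
    """
    value = value.strip()
    m = _TERM_ID_RE.match(value)
    if m is None:
        raise UnknownTermError(value, f"malformed term identifier: {value!r}")
    return f"{m.group(1).upper()}:{m.group(2)}"


@dataclass(frozen=True)
class Term:
    """A single ontology class."""

    id: str
    name: str = ""
    parents: FrozenSet[str] = frozenset()
    alt_ids: FrozenSet[str] = frozenset()
    obsolete: bool = False
    replaced_by: tuple[str, ...] = ()


@dataclass
class OntologyGraph:
    """Validated DAG of ontology terms over the subclass relation.

    ``terms`` maps primary id -> :class:`Term` (obsolete terms are retained
    but carry no edges).  Ancestor queries run over an internal
    ``networkx.DiGraph`` with child -> parent edges and are memoized, since
    profile-closure construction hits the same terms repeatedly.
    """

    terms: dict[str, Term]
    _dag: nx.DiGraph = field(init=False, repr=False)
    _alt_index: dict[str, str] = field(init=False, repr=False)
    _ancestor_cache: dict[str, frozenset] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._validate_and_index()

    # -- construction -------------------------------------------------

    def _validate_and_index(self) -> None:
        dag = nx.DiGraph()
        alt_index: dict[str, str] = {}
        for term in self.terms.values():
            if not term.obsolete:
                dag.add_node(term.id)
            for alt in term.alt_ids:
                if alt in self.terms:
                    raise OntologyValidationError(
                        f"alt_id {alt} collides with a primary term id"
                    )
                if alt in alt_index:
                    raise OntologyValidationError(
                        f"alt_id {alt} claimed by both {alt_index[alt]} and {term.id}"
                    )
                alt_index[alt] = term.id

        for term in self.terms.values():
            if term.obsolete:
                if term.parents:
                    raise OntologyValidationError(
                        f"obsolete term {term.id} must not carry is_a edges"
                    )
                continue
            for parent in term.parents:
                target = self.terms.get(parent)
                if target is None:
                    raise OntologyValidationError(
                        f"term {term.id} has unknown parent {parent}"
                    )
                if target.obsolete:
                    raise OntologyValidationError(
                        f"term {term.id} has obsolete parent {parent}"
                    )
                dag.add_edge(term.id, parent)

        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
            raise OntologyValidationError(f"is_a cycle detected: {path}")

        self._dag = dag
        self._alt_index = alt_index
        self._ancestor_cache = {}

    # -- basic views ---------------------------------------------------

    @property
    def roots(self) -> frozenset:
        """Primary, non-obsolete terms with no parents (multiple roots allowed)."""
        return frozenset(
            t.id for t in self.terms.values() if not t.obsolete and not t.parents
        )

    @property
    def n_edges(self) -> int:
        return self._dag.number_of_edges()

    def active_terms(self) -> frozenset:
        """All non-obsolete primary term ids."""
        return frozenset(t.id for t in self.terms.values() if not t.obsolete)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt_index

    # -- queries -------------------------------------------------------

    def resolve(self, term_id: str, follow_replaced_by: bool = False) -> str:
        """Map a term id (primary or alt_id) to its primary id.

        Obsolete terms resolve to themselves unless ``follow_replaced_by``
        is set and a replacement exists.  Unknown ids raise
        :class:`UnknownTermError`.
        """
        term_id = normalize_term_id(term_id)
        primary = term_id if term_id in self.terms else self._alt_index.get(term_id)
        if primary is None:
            raise UnknownTermError(term_id)
        term = self.terms[primary]
        if term.obsolete and follow_replaced_by and term.replaced_by:
            return self.resolve(term.replaced_by[0], follow_replaced_by=True)
        return primary

    def ancestors(self, term_id: str) -> frozenset:
        """All strict superclasses of ``term_id`` (the term itself excluded)."""
        primary = self.resolve(term_id)
        if self.terms[primary].obsolete:
            raise UnknownTermError(
                primary, f"term {primary} is obsolete and carries no edges"
            )
        cached = self._ancestor_cache.get(primary)
        if cached is None:
            # child->parent edges: superclasses are reachable nodes.
            cached = frozenset(nx.descendants(self._dag, primary))
            self._ancestor_cache[primary] = cached
        return cached

    def closure(self, term_ids: Iterable[str]) -> frozenset:
        """Superclass closure Cl(X) = X plus all ancestors of members of X.

        ``closure(frozenset())`` is the empty set: empty queries are
        rejected upstream, and this keeps the extensivity/monotonicity laws
        clean.
        """
        out: set[str] = set()
        for t in term_ids:
            primary = self.resolve(t)
            out.add(primary)
            out.update(self.ancestors(primary))
        return frozenset(out)


# -- OBO ingestion -----------------------------------------------------


def parse_obo(path, extra_relations: Iterable[str] = ()) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into a validated :class:`OntologyGraph`.

    Recognized tags: ``id``, ``name``, ``alt_id``, ``is_a`` (trailing
    ``! comment`` stripped by the reader), ``is_obsolete``, ``replaced_by``.
    All other tags are ignored.  Obsolete terms are retained but flagged
    and stripped of edges.  ``extra_relations`` names additional
    ``relationship:`` types (e.g. ``part_of``) to treat as subclass-like
    edges; the default is ``is_a`` only.

    Raises :class:`OboParseError` for unreadable input and
    :class:`OntologyValidationError` for structural violations (cycles,
    dangling parents, duplicate alt_ids).
    """
    import io

    try:
        with open(path) as handle:
            text = handle.read()
        multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except OntologyValidationError:
        raise
    except Exception as exc:  # obonet raises ValueError for malformed stanzas
        raise OboParseError(f"cannot parse OBO file {path!r}: {exc}") from exc

    # obonet silently materializes a node for any is_a target that lacks a
    # stanza; cross-check against the ids actually declared in the file so
    # dangling parents surface as validation errors.
    declared = set(re.findall(r"^id:\s*(\S+)", text, flags=re.MULTILINE))

    keep_keys = {"is_a"} | set(extra_relations)
    terms: dict[str, Term] = {}
    for node, data in multigraph.nodes(data=True):
        if node not in declared:
            raise OntologyValidationError(
                f"term {node} is referenced as a parent but never declared"
            )
        try:
            node_id = normalize_term_id(node)
        except UnknownTermError as exc:
            raise OboParseError(f"malformed term id in stanza: {node!r}") from exc
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: set[str] = set()
        if not obsolete:
            parents.update(data.get("is_a", []))
            for rel in data.get("relationship", []):
                parts = rel.split()
                if len(parts) >= 2 and parts[0] in keep_keys:
                    parents.add(parts[1])
        terms[node_id] = Term(
            id=node_id,
            name=data.get("name", ""),
            parents=frozenset(normalize_term_id(p) for p in parents),
            alt_ids=frozenset(normalize_term_id(a) for a in data.get("alt_id", [])),
            obsolete=obsolete,
            replaced_by=tuple(
                normalize_term_id(r) for r in data.get("replaced_by", [])
            ),
        )
    if not terms:
        raise OboParseError(f"OBO file {path!r} contains no [Term] stanzas")

    graph = OntologyGraph(terms)
    logger.info(
        "parsed ontology: %d terms (%d obsolete), %d is_a edges, %d roots",
        len(terms),
        sum(t.obsolete for t in terms.values()),
        graph.n_edges,
        len(graph.roots),
    )
    return graph


# Thin functional aliases mirroring the operation-style API.


def resolve(term_id: str, graph: OntologyGraph, **kwargs) -> str:
    return graph.resolve(term_id, **kwargs)


def ancestors(term_id: str, graph: OntologyGraph) -> frozenset:
    return graph.ancestors(term_id)


def closure(term_ids: Iterable[str], graph: OntologyGraph) -> frozenset:
    return graph.closure(term_ids)
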