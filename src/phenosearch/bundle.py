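"""Serialized index bundle: one canonical ontology + corpus + IC table.

A bundle is the unit the command-line workflows pass between ``build``
and ``query``/``evaluate``/``benchmark``.  It is a versioned JSON
container written deterministically (sorted keys, sorted collections, no
timestamps) so that rebuilding from identical inputs yields an identical
content digest.  Loaders refuse mismatched format versions.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Optional

from .corpus import Corpus, EntityProfile, ICTable, compute_ic
from .errors import CorpusFormatError
from .ontology import OntologyGraph, Term
from .similarity import MappingTable

FORMAT_NAME = "phenosearch-bundle"
FORMAT_VERSION = 1


@dataclass
class IndexBundle:
    """Everything one search deployment needs, plus build provenance."""

    ontology: OntologyGraph
    corpus: Corpus
    ic: ICTable
    mapping: Optional[MappingTable] = None
    metadata: dict = None

    def __post_init__(self):
        if self.metadata is None:
            self.metadata = {}
        if self.ic.n_entities != self.corpus.n_entities:
            raise CorpusFormatError(
                "IC table and corpus disagree on entity count "
                f"({self.ic.n_entities} vs {self.corpus.n_entities})"
            )


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _payload(bundle: IndexBundle) -> dict:
    terms = [
        {
            "id": t.id,
            "name": t.name,
            "parents": sorted(t.parents),
            "alt_ids": sorted(t.alt_ids),
            "obsolete": t.obsolete,
            "replaced_by": list(t.replaced_by),
        }
        for t in (bundle.ontology.terms[tid] for tid in sorted(bundle.ontology.terms))
    ]
    entities = [
        {
            "entity_id": p.entity_id,
            "entity_type": p.entity_type,
            "species": p.species,
            "terms": sorted(p.annotated_terms),
        }
        for p in (bundle.corpus.profiles[e] for e in sorted(bundle.corpus.profiles))
    ]
    mapping = None
    if bundle.mapping is not None:
        mapping = {
            "provenance": bundle.mapping.provenance,
            "pairs": {s: sorted(t) for s, t in sorted(bundle.mapping.pairs.items())},
        }
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "ontology": {"terms": terms},
        "corpus": {"entities": entities},
        "ic": {
            "n_entities": bundle.ic.n_entities,
            "log_base": "e",
            "values": {t: bundle.ic.values[t] for t in sorted(bundle.ic.values)},
        },
        "mapping": mapping,
        "metadata": bundle.metadata,
    }


def save_bundle(bundle: IndexBundle, path) -> str:
    """Write the bundle; returns its sha256 content digest."""
    text = json.dumps(_payload(bundle), sort_keys=True, separators=(",", ":"))
    with open(path, "w") as handle:
        handle.write(text)
        handle.write("\n")
    return hashlib.sha256(text.encode()).hexdigest()


def load_bundle(path) -> IndexBundle:
    """Read a bundle back; closures are recomputed from annotated terms."""
    with open(path) as handle:
        data = json.load(handle)
    if data.get("format") != FORMAT_NAME or data.get("version") != FORMAT_VERSION:
        raise CorpusFormatError(
            f"{path!r} is not a {FORMAT_NAME} v{FORMAT_VERSION} file "
            f"(found {data.get('format')!r} v{data.get('version')!r})"
        )
    graph = OntologyGraph(
        {
            t["id"]: Term(
                id=t["id"],
                name=t["name"],
                parents=frozenset(t["parents"]),
                alt_ids=frozenset(t["alt_ids"]),
                obsolete=t["obsolete"],
                replaced_by=tuple(t["replaced_by"]),
            )
            for t in data["ontology"]["terms"]
        }
    )
    profiles = {}
    for e in data["corpus"]["entities"]:
        annotated = frozenset(e["terms"])
        profiles[e["entity_id"]] = EntityProfile(
            entity_id=e["entity_id"],
            entity_type=e["entity_type"],
            species=e["species"],
            annotated_terms=annotated,
            closed_terms=graph.closure(annotated),
        )
    corpus = Corpus(profiles)
    ic = ICTable(
        values=dict(data["ic"]["values"]),
        n_entities=data["ic"]["n_entities"],
        log_base=math.e,
    )
    mapping = None
    if data.get("mapping"):
        mapping = MappingTable(
            pairs={s: frozenset(t) for s, t in data["mapping"]["pairs"].items()},
            provenance=data["mapping"].get("provenance", ""),
        )
    return IndexBundle(
        ontology=graph, corpus=corpus, ic=ic, mapping=mapping,
        metadata=data.get("metadata", {}),
    )
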