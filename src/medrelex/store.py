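"""RDF annotation store and form-based semantic queries.

Entity mentions and relation triples are written to an RDF graph:

* one resource per mention (IRI derived deterministically from the
  document id and character span), typed by its category class and
  carrying surface form, concept id, semantic type, document IRI and
  start/end offsets;
* one direct statement per relation triple, with the relation name as
  predicate IRI, plus a reified annotation node holding sentence-level
  provenance (sentence text and offsets — both are emitted).

Queries are (source, relation, target) specifications where each field is
a category name, a concept term/id, or a wildcard; answers are the
matching relation annotations joined with their sentence text and
document.  Execution is native graph-pattern matching, equivalent to the
obvious SPARQL reformulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union
from urllib.parse import quote

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from .knowledge import Category, RELATION_NAMES, normalize_term
from .ner import EntityMention
from .relations import RelationTriple
from .segmentation import Document

__all__ = [
    "MR",
    "QueryAnswer",
    "QuerySpec",
    "WILDCARD",
    "answer",
    "build_ontology",
    "entity_iri",
    "load_graph",
    "to_rdf",
]

#: Vocabulary namespace (classes Problem/Treatment/Test/Other, the six
#: relation properties, and the provenance predicates).
MR = Namespace("http://medrelex.example.org/schema#")
DEFAULT_BASE = "http://medrelex.example.org/annotation/"
WILDCARD = "*"


def build_ontology() -> Graph:
    """The small self-contained relation-model ontology.

    Classes for the entity categories; the six relations as properties
    with their default domain/range categories.
    """
    g = Graph()
    g.bind("mr", MR)
    for cat in Category:
        g.add((MR[cat.value], RDF.type, RDFS.Class))
    domains = {
        "treats": ("Treatment", "Problem"),
        "prevents": ("Treatment", "Problem"),
        "diagnoses": ("Test", "Problem"),
        "causes": ("Problem", "Problem"),
        "complicates": ("Problem", "Problem"),
        "sign_or_symptom_of": ("Problem", "Problem"),
    }
    for rel in RELATION_NAMES:
        prop = MR[rel]
        g.add((prop, RDF.type, RDF.Property))
        dom, rng = domains[rel]
        g.add((prop, RDFS.domain, MR[dom]))
        g.add((prop, RDFS.range, MR[rng]))
    return g


def entity_iri(doc_id: str, start: int, end: int, base: str = DEFAULT_BASE) -> URIRef:
    """Deterministic mention IRI — re-annotation is idempotent."""
    return URIRef(f"{base}{quote(doc_id, safe='')}#e{start}-{end}")


def _doc_iri(doc_id: str, base: str) -> URIRef:
    return URIRef(f"{base}{quote(doc_id, safe='')}")


def to_rdf(
    document: Document,
    mentions: list[EntityMention],
    triples: list[RelationTriple],
    base: str = DEFAULT_BASE,
    graph: Graph | None = None,
) -> Graph:
    """Serialize mentions and relation triples for one document as RDF."""
    g = graph if graph is not None else Graph()
    g.bind("mr", MR)
    doc = _doc_iri(document.doc_id, base)
    g.add((doc, RDF.type, MR.Document))
    for m in mentions:
        e = entity_iri(m.doc_id, m.start, m.end, base)
        g.add((e, RDF.type, MR[m.category]))
        g.add((e, MR.surfaceForm, Literal(m.surface)))
        g.add((e, MR.concept, Literal(m.concept_id)))
        g.add((e, MR.semanticType, Literal(m.semantic_type)))
        g.add((e, MR.inDocument, doc))
        g.add((e, MR.beginIndex, Literal(m.start, datatype=XSD.integer)))
        g.add((e, MR.endIndex, Literal(m.end, datatype=XSD.integer)))
    for t in triples:
        s = entity_iri(t.source.doc_id, t.source.start, t.source.end, base)
        o = entity_iri(t.target.doc_id, t.target.start, t.target.end, base)
        g.add((s, MR[t.relation], o))
        ann = URIRef(
            f"{base}{quote(t.source.doc_id, safe='')}"
            f"#rel-{t.source.start}-{t.source.end}-{t.relation}-{t.target.start}-{t.target.end}"
        )
        g.add((ann, RDF.type, MR.RelationAnnotation))
        g.add((ann, MR.source, s))
        g.add((ann, MR.relationName, Literal(t.relation)))
        g.add((ann, MR.target, o))
        g.add((ann, MR.inDocument, doc))
        if t.pattern_id:
            g.add((ann, MR.patternId, Literal(t.pattern_id)))
        ss, se = t.source.sent_start, t.source.sent_end
        if 0 <= ss < se <= len(document.text):
            g.add((ann, MR.sentenceText, Literal(document.text[ss:se])))
            g.add((ann, MR.sentenceBegin, Literal(ss, datatype=XSD.integer)))
            g.add((ann, MR.sentenceEnd, Literal(se, datatype=XSD.integer)))
    return g


def load_graph(path: Union[str, Path]) -> Graph:
    path = Path(path)
    fmt = {"ttl": "turtle", "nt": "nt", "xml": "xml"}.get(path.suffix.lstrip("."), "turtle")
    g = Graph()
    g.parse(str(path), format=fmt)
    return g


@dataclass(frozen=True)
class QuerySpec:
    """Form-based query; each field is a category, a term/concept id, or ``*``."""

    source: str = WILDCARD
    relation: str = WILDCARD
    target: str = WILDCARD


@dataclass(frozen=True)
class QueryAnswer:
    sentence_text: str | None
    document: str
    relation: str
    source_surface: str
    source_concept: str
    target_surface: str
    target_concept: str


_CATEGORY_NAMES = {c.value for c in Category}


def _entity_matches(g: Graph, entity: URIRef, spec: str) -> bool:
    if spec == WILDCARD:
        return True
    if spec in _CATEGORY_NAMES:
        return (entity, RDF.type, MR[spec]) in g
    want = normalize_term(spec)
    surface = g.value(entity, MR.surfaceForm)
    concept = g.value(entity, MR.concept)
    if surface is not None and normalize_term(str(surface)) == want:
        return True
    return concept is not None and str(concept) == spec


def answer(store: Graph, query: QuerySpec) -> list[QueryAnswer]:
    """Return every relation annotation matching the query spec.

    Wildcards match everything, so the all-wildcard query enumerates all
    stored relation statements.
    """
    out: list[QueryAnswer] = []
    for ann in store.subjects(RDF.type, MR.RelationAnnotation):
        rel = store.value(ann, MR.relationName)
        src = store.value(ann, MR.source)
        tgt = store.value(ann, MR.target)
        if rel is None or src is None or tgt is None:
            continue
        if query.relation not in (WILDCARD, str(rel)):
            continue
        if not _entity_matches(store, src, query.source):
            continue
        if not _entity_matches(store, tgt, query.target):
            continue
        sent = store.value(ann, MR.sentenceText)
        doc = store.value(ann, MR.inDocument)
        out.append(
            QueryAnswer(
                sentence_text=None if sent is None else str(sent),
                document="" if doc is None else str(doc),
                relation=str(rel),
                source_surface=str(store.value(src, MR.surfaceForm) or ""),
                source_concept=str(store.value(src, MR.concept) or ""),
                target_surface=str(store.value(tgt, MR.surfaceForm) or ""),
                target_concept=str(store.value(tgt, MR.concept) or ""),
            )
        )
    out.sort(
        key=lambda a: (a.document, a.relation, a.source_surface, a.target_surface)
    )
    return out
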