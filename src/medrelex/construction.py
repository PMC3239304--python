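"""Semi-automatic pattern building.

Workflow: seed concept pairs known to stand in a target relation →
focused literature query strings (MeSH-subheading style) → field
extraction from PMC-style NXML articles → selection of sentences that
mention both concepts of some seed pair → conservative pattern skeletons
for human curation.  Queries are emitted as strings only; the corpus is
always read from local files.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from lxml import etree

from .knowledge import Lexicon, SeedPair, SemanticSchema
from .ner import EntityMention, NERConfig, recognize
from .relations import (
    DEFAULT_SLOT_CATEGORIES,
    PatternError,
    PatternSpec,
    compile_pattern,
)
from .segmentation import (
    Document,
    POSTagger,
    SentenceSpan,
    Token,
    segment_document,
    tokenize,
)

__all__ = [
    "CandidatePattern",
    "CorpusQuery",
    "NoQualifierError",
    "SUBHEADINGS",
    "build_query",
    "extract_article_text",
    "induce_skeleton",
    "parse_query",
    "select_sentences",
]

#: MeSH-style subheadings approximating a relation ("therapy", "prevention
#: and control", "diagnosis").  Relations without a qualifier cannot drive
#: corpus selection and raise NoQualifierError.
SUBHEADINGS: dict[str, str] = {
    "treats": "th",
    "prevents": "pc",
    "diagnoses": "di",
}


class NoQualifierError(ValueError):
    """No indexing qualifier exists for the requested relation."""


@dataclass(frozen=True)
class CorpusQuery:
    query_string: str
    relation: str
    problem_term: str
    treatment_terms: tuple[str, ...]


def build_query(
    problem_term: str, treatment_terms: Sequence[str], relation: str
) -> CorpusQuery:
    """Build a ``<problem>/<subheading>[MAJR] AND (<t1> OR ...)`` query string.

    [MAJR] marks the problem as a major topic (which implies MeSH-mode
    search for it); the treatment clause is an OR over the seed terms,
    unparenthesized when there is only one.
    """
    if relation not in SUBHEADINGS:
        raise NoQualifierError(f"no qualifier for relation {relation!r}")
    if not problem_term or not treatment_terms:
        raise ValueError("problem term and treatment terms must be non-empty")
    sub = SUBHEADINGS[relation]
    terms = tuple(treatment_terms)
    clause = terms[0] if len(terms) == 1 else "(" + " OR ".join(terms) + ")"
    return CorpusQuery(
        query_string=f"{problem_term}/{sub}[MAJR] AND {clause}",
        relation=relation,
        problem_term=problem_term,
        treatment_terms=terms,
    )


_QUERY_RE = re.compile(r"^(?P<problem>.+)/(?P<sub>[a-z]+)\[MAJR\] AND (?P<clause>.+)$")


def parse_query(query_string: str) -> tuple[str, str, tuple[str, ...]]:
    """Invert build_query: return (problem_term, subheading, treatment_terms)."""
    m = _QUERY_RE.match(query_string)
    if not m:
        raise ValueError(f"unparseable query string: {query_string!r}")
    clause = m.group("clause")
    if clause.startswith("(") and clause.endswith(")"):
        clause = clause[1:-1]
    return m.group("problem"), m.group("sub"), tuple(clause.split(" OR "))


_WS_RE = re.compile(r"\s+")


def _element_text(el) -> str:
    return _WS_RE.sub(" ", " ".join(el.itertext())).strip()


def extract_article_text(
    source: Union[str, Path, bytes], doc_id: str | None = None
) -> Document:
    """Extract title, abstract and body text from a PMC-style NXML article.

    The document text is the present fields joined with newlines, in that
    order, with all markup stripped.  Malformed XML raises; an article
    with none of the three fields yields empty text with a warning.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
        did = doc_id or "article"
    else:
        path = Path(source)
        root = etree.parse(str(path)).getroot()
        did = doc_id or path.stem
    parts = []
    for xpath in (".//article-title", ".//abstract", ".//body"):
        el = root.find(xpath)
        if el is not None:
            text = _element_text(el)
            if text:
                parts.append(text)
    if not parts:
        warnings.warn(f"article {did!r}: no title, abstract or body found")
    return Document(doc_id=did, text="\n".join(parts))


def select_sentences(
    documents: Iterable[Document],
    lexicon: Lexicon,
    schema: SemanticSchema,
    seeds: Iterable[SeedPair],
    relation: str,
    config: NERConfig | None = None,
    tagger: POSTagger | None = None,
    abbreviations: Iterable[str] | None = None,
) -> list[tuple[Document, SentenceSpan, SeedPair]]:
    """Keep sentences mentioning both concepts of a seed pair of ``relation``.

    A sentence is emitted once per distinct matching seed pair, so a
    sentence instantiating two seed pairs appears twice.
    """
    wanted = [s for s in seeds if s.relation == relation]
    out: list[tuple[Document, SentenceSpan, SeedPair]] = []
    for doc in documents:
        for sent in segment_document(doc, abbreviations):
            mentions = recognize(sent, lexicon, schema, config, tagger, doc_id=doc.doc_id)
            concepts = {m.concept_id for m in mentions}
            for seed in wanted:
                if seed.concept1_id in concepts and seed.concept2_id in concepts:
                    out.append((doc, sent, seed))
    return out


@dataclass
class CandidatePattern:
    """An induced pattern skeleton awaiting human curation."""

    relation: str
    template: str
    source_sentence: str
    seed_pair: SeedPair | None = None
    status: str = "candidate"

    def accept(self) -> None:
        self._transition("accepted")

    def reject(self) -> None:
        self._transition("rejected")

    def _transition(self, new: str) -> None:
        if self.status != "candidate":
            raise ValueError(f"cannot move from {self.status!r} to {new!r}")
        self.status = new


#: Tokens generalized to a gap during induction (plus numbers).
DEFAULT_CLOSED_CLASS: frozenset[str] = frozenset(
    "a an the this that these those each every some any no".split()
)
_NUM_RE = re.compile(r"\d+(?:[.,]\d+)*")
_SENT_PUNCT = frozenset({".", "!", "?", ",", ";", ":"})


def induce_skeleton(
    tokens: Sequence[Token],
    pair: tuple[EntityMention, EntityMention],
    relation: str,
    seed_pair: SeedPair | None = None,
    n_context: int = 2,
    closed_class: frozenset[str] | None = None,
) -> CandidatePattern:
    """Induce a conservative pattern skeleton from an example sentence.

    The tokens between the two mentions become literals (closed-class
    words and numbers become gaps), the mentions become E1/E2 slots at
    their textual positions, and up to ``n_context`` non-punctuation
    tokens on each side are kept as extra literals.  Slot assignment
    follows the relation's default categories; when neither mention
    matches them, slots go in textual order with explicit category
    constraints.
    """
    closed = DEFAULT_CLOSED_CLASS if closed_class is None else closed_class
    m1, m2 = sorted(pair, key=lambda m: m.start)
    if m1.end > m2.start:
        raise ValueError("mentions overlap; cannot induce a pattern")
    defaults = DEFAULT_SLOT_CATEGORIES[relation]
    if (m1.category, m2.category) == defaults:
        slot1, slot2 = "E1", "E2"
    elif (m2.category, m1.category) == defaults:
        slot1, slot2 = "E2", "E1"
    else:
        slot1 = f"E1[{m1.category}]"
        slot2 = f"E2[{m2.category}]"

    def generalize(tok: Token) -> str:
        low = tok.text.lower()
        if low in closed or _NUM_RE.fullmatch(tok.text):
            return "..."
        return tok.text

    before = [t for t in tokens if t.end <= m1.start and t.text not in _SENT_PUNCT]
    between = [t for t in tokens if m1.end <= t.start and t.end <= m2.start]
    after = [t for t in tokens if t.start >= m2.end and t.text not in _SENT_PUNCT]
    parts = (
        [generalize(t) for t in before[-n_context:]]
        + [slot1]
        + [generalize(t) for t in between]
        + [slot2]
        + [generalize(t) for t in after[:n_context]]
    )
    # collapse runs of gaps so the template stays minimal
    collapsed: list[str] = []
    for p in parts:
        if p == "..." and collapsed and collapsed[-1] == "...":
            continue
        collapsed.append(p)
    template = " ".join(collapsed)
    spec = PatternSpec(pattern_id="candidate", relation=relation, template=template)
    compile_pattern(spec)  # raises PatternError if the skeleton is unusable
    sentence_text = " ".join(t.text for t in tokens)
    return CandidatePattern(
        relation=relation,
        template=template,
        source_sentence=sentence_text,
        seed_pair=seed_pair,
    )
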