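"""Medical entity recognition over noun-phrase chunks.

The three-step recipe: (1) segment text into sentences and base noun
phrases, (2) map chunk substrings to lexicon concepts with longest-match
dictionary lookup, (3) filter the candidates through the stoplist and a
semantic-type restriction, then disambiguate to one mention per span.
Mentions never cross chunk boundaries, which is what chunk-first
segmentation buys in boundary precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Union

from .knowledge import (
    Category,
    Lexicon,
    SemanticSchema,
    category_of,
    lookup,
    term_key,
)
from .segmentation import (
    Document,
    HeuristicPOSTagger,
    POSTagger,
    PhraseSpan,
    SentenceSpan,
    chunk_noun_phrases,
    segment_document,
    tokenize,
)

__all__ = [
    "EntityMention",
    "NERConfig",
    "annotate_document",
    "default_allowed_types",
    "disambiguate",
    "filter_stoplist",
    "map_chunks",
    "mention_from_dict",
    "mention_to_dict",
    "recognize",
    "restrict_types",
]


@dataclass(frozen=True)
class EntityMention:
    """A typed, categorized text span anchored to a sentence and document."""

    doc_id: str
    start: int
    end: int
    surface: str
    concept_id: str
    semantic_type: str
    category: str
    sent_start: int = -1
    sent_end: int = -1


@dataclass(frozen=True)
class NERConfig:
    """Recognition switches.

    ``allowed_types=None`` means "every schema type whose category is not
    Other" — i.e. only types that can be sources or targets of the
    targeted relations survive.  ``disambiguation_priority`` ranks
    categories when one span maps to several candidates.
    """

    apply_stoplist: bool = True
    allowed_types: frozenset[str] | None = None
    disambiguation_priority: tuple[str, ...] = ("Problem", "Treatment", "Test")


def default_allowed_types(schema: SemanticSchema) -> frozenset[str]:
    return frozenset(
        name for name, st in schema.types.items() if st.category is not Category.OTHER
    )


def map_chunks(
    chunks: Sequence[PhraseSpan],
    lexicon: Lexicon,
    schema: SemanticSchema,
    doc_id: str = "",
    sentence: SentenceSpan | None = None,
) -> list[EntityMention]:
    """Dictionary-map each chunk to candidate mentions.

    One candidate per (matched span, concept id, semantic type); a concept
    with two semantic types therefore yields two same-span candidates.
    """
    sent_start = sentence.start if sentence is not None else -1
    sent_end = sentence.end if sentence is not None else -1
    candidates: list[EntityMention] = []
    for chunk in chunks:
        toks = chunk.tokens or tuple(tokenize(chunk.text, base=chunk.start))
        for m in lookup(lexicon, toks):
            surface = chunk.text[m.start - chunk.start : m.end - chunk.start]
            for cid in m.concept_ids:
                for stype in lexicon.concepts[cid].semantic_types:
                    candidates.append(
                        EntityMention(
                            doc_id=doc_id,
                            start=m.start,
                            end=m.end,
                            surface=surface,
                            concept_id=cid,
                            semantic_type=stype,
                            category=category_of(schema, stype).value,
                            sent_start=sent_start,
                            sent_end=sent_end,
                        )
                    )
    return candidates


def filter_stoplist(
    candidates: Iterable[EntityMention], stoplist: Iterable[str]
) -> list[EntityMention]:
    """Drop candidates whose normalized surface is stoplisted."""
    stop = set(stoplist)
    return [c for c in candidates if term_key(c.surface) not in stop]


def restrict_types(
    candidates: Iterable[EntityMention], allowed_types: Iterable[str]
) -> list[EntityMention]:
    """Keep only candidates of an allowed semantic type."""
    allowed = set(allowed_types)
    return [c for c in candidates if c.semantic_type in allowed]


def disambiguate(
    candidates: Sequence[EntityMention],
    priority: Sequence[str] = ("Problem", "Treatment", "Test"),
) -> list[EntityMention]:
    """Resolve to exactly one mention per surviving span.

    Overlapping spans: longest span first, earlier start breaks ties.
    Within a span: the candidate whose category is earliest in the
    priority wins; remaining ties break lexicographically on
    (semantic_type, concept_id).  The output is non-overlapping and
    sorted by start offset.
    """
    rank = {c: i for i, c in enumerate(priority)}
    by_span: dict[tuple[int, int], list[EntityMention]] = {}
    for c in candidates:
        by_span.setdefault((c.start, c.end), []).append(c)
    accepted: list[EntityMention] = []
    for span in sorted(by_span, key=lambda s: (-(s[1] - s[0]), s[0])):
        if any(span[0] < m.end and m.start < span[1] for m in accepted):
            continue
        best = min(
            by_span[span],
            key=lambda c: (rank.get(c.category, len(rank)), c.semantic_type, c.concept_id),
        )
        accepted.append(best)
    return sorted(accepted, key=lambda m: (m.start, m.end))


def recognize(
    sentence: Union[str, SentenceSpan],
    lexicon: Lexicon,
    schema: SemanticSchema,
    config: NERConfig | None = None,
    tagger: POSTagger | None = None,
    doc_id: str = "",
) -> list[EntityMention]:
    """Full recognition pipeline for one sentence.

    Equivalent to ``disambiguate(restrict_types(filter_stoplist(
    map_chunks(chunk(sentence)))))`` and a pure function of its inputs.
    """
    if isinstance(sentence, str):
        sentence = SentenceSpan(start=0, end=len(sentence), text=sentence, doc_id=doc_id)
    cfg = config or NERConfig()
    tagger = tagger or HeuristicPOSTagger()
    tokens = tagger.tag(tokenize(sentence))
    chunks = chunk_noun_phrases(tokens)
    cands = map_chunks(
        chunks, lexicon, schema, doc_id=doc_id or sentence.doc_id, sentence=sentence
    )
    if cfg.apply_stoplist:
        cands = filter_stoplist(cands, lexicon.stoplist)
    allowed = cfg.allowed_types if cfg.allowed_types is not None else default_allowed_types(schema)
    cands = restrict_types(cands, allowed)
    return disambiguate(cands, cfg.disambiguation_priority)


def annotate_document(
    document: Document,
    lexicon: Lexicon,
    schema: SemanticSchema,
    config: NERConfig | None = None,
    tagger: POSTagger | None = None,
    abbreviations: Iterable[str] | None = None,
) -> tuple[list[SentenceSpan], list[EntityMention]]:
    """Segment a document and recognize mentions in every sentence."""
    sentences = segment_document(document, abbreviations)
    mentions: list[EntityMention] = []
    for sent in sentences:
        mentions.extend(
            recognize(sent, lexicon, schema, config, tagger, doc_id=document.doc_id)
        )
    return sentences, mentions


def mention_to_dict(m: EntityMention) -> dict:
    return {
        "doc_id": m.doc_id,
        "start": m.start,
        "end": m.end,
        "surface": m.surface,
        "concept_id": m.concept_id,
        "semantic_type": m.semantic_type,
        "category": m.category,
        "sent_start": m.sent_start,
        "sent_end": m.sent_end,
    }


def mention_from_dict(d: dict) -> EntityMention:
    return EntityMention(
        doc_id=d["doc_id"],
        start=int(d["start"]),
        end=int(d["end"]),
        surface=d["surface"],
        concept_id=d["concept_id"],
        semantic_type=d["semantic_type"],
        category=d["category"],
        sent_start=int(d.get("sent_start", -1)),
        sent_end=int(d.get("sent_end", -1)),
    )
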