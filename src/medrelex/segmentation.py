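"""Sentence splitting, tokenization and base noun-phrase chunking.

Segmentation runs *before* concept mapping: mapping dictionary terms onto
pre-chunked noun phrases rather than raw text is what keeps entity
boundaries clean (sentence splitters that ignore biomedical abbreviations
notoriously cut sentences in the middle of entities, e.g. after "i.v.").

All offsets are 0-based, half-open, character-level offsets into the
owning document's text, so every span round-trips through slicing.

POS tagging is pluggable (any object with ``tag(tokens) -> tokens``); the
shipped :class:`HeuristicPOSTagger` uses closed-class word lists plus
suffix heuristics so the pipeline runs with no model download.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Protocol, Sequence, Union

__all__ = [
    "DEFAULT_ABBREVIATIONS",
    "Document",
    "HeuristicPOSTagger",
    "POSTagger",
    "PhraseSpan",
    "SentenceSpan",
    "Token",
    "chunk_noun_phrases",
    "segment_document",
    "split_sentences",
    "tokenize",
]


@dataclass(frozen=True)
class Document:
    """A plain-text document with a run-unique identifier."""

    doc_id: str
    text: str
    source_uri: str | None = None

    def __post_init__(self):
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class SentenceSpan:
    start: int
    end: int
    text: str
    doc_id: str = ""


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    pos_tag: str | None = None


@dataclass(frozen=True)
class PhraseSpan:
    """A base noun-phrase chunk (candidate span for entity mapping)."""

    start: int
    end: int
    text: str
    tokens: tuple[Token, ...] = ()


#: Abbreviations after which a period never ends a sentence.
DEFAULT_ABBREVIATIONS: frozenset[str] = frozenset(
    {
        "e.g.", "i.e.", "i.v.", "i.m.", "p.o.", "b.i.d.", "t.i.d.", "q.d.",
        "et al.", "fig.", "figs.", "dr.", "vs.", "ca.", "resp.", "approx.",
        "no.", "spp.", "subsp.", "cf.", "wt.", "vol.", "pp.",
    }
)

_TERMINAL_RE = re.compile(r"[.!?]+")


def _ends_with_abbreviation(text: str, end: int, abbreviations: frozenset[str]) -> bool:
    for abbr in abbreviations:
        k = len(abbr)
        if end >= k and text[end - k : end].lower() == abbr:
            if end == k or not text[end - k - 1].isalnum():
                return True
    return False


def split_sentences(
    text: str,
    abbreviations: Iterable[str] | None = None,
    doc_id: str = "",
) -> list[SentenceSpan]:
    """Split text into sentence spans.

    A boundary is placed after terminal punctuation ``. ! ?`` followed by
    whitespace and an uppercase letter or digit, except when the period
    closes a listed abbreviation.  The concatenation of the spans plus the
    inter-span gaps reconstructs the input exactly; spans themselves are
    trimmed of outer whitespace.
    """
    abbrevs = (
        DEFAULT_ABBREVIATIONS
        if abbreviations is None
        else frozenset(a.lower() for a in abbreviations)
    )
    boundaries: list[int] = []
    for m in _TERMINAL_RE.finditer(text):
        end = m.end()
        j = end
        while j < len(text) and text[j].isspace():
            j += 1
        if j == end or j >= len(text):
            continue  # no whitespace after, or nothing follows
        if not (text[j].isupper() or text[j].isdigit()):
            continue
        if m.group().endswith(".") and _ends_with_abbreviation(text, end, abbrevs):
            continue
        boundaries.append(end)
    spans: list[SentenceSpan] = []
    prev = 0
    for b in boundaries + [len(text)]:
        seg = text[prev:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        s, e = prev + lead, b - trail
        if e > s:
            spans.append(SentenceSpan(start=s, end=e, text=text[s:e], doc_id=doc_id))
        prev = b
    return spans


def segment_document(
    document: Document, abbreviations: Iterable[str] | None = None
) -> list[SentenceSpan]:
    return split_sentences(document.text, abbreviations, doc_id=document.doc_id)


# Words keep internal hyphens/apostrophes ("amoxicillin-clavulanate" is one
# token); all other non-space characters tokenize individually.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['\-][A-Za-z0-9]+)*|\S")


def tokenize(sentence: Union[str, SentenceSpan], base: int = 0) -> list[Token]:
    """Tokenize a sentence (or raw string) into offset-carrying tokens."""
    if isinstance(sentence, SentenceSpan):
        text, base = sentence.text, sentence.start
    else:
        text = sentence
    return [
        Token(text=m.group(), start=base + m.start(), end=base + m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


class POSTagger(Protocol):
    def tag(self, tokens: Sequence[Token]) -> list[Token]: ...


_DETERMINERS = frozenset(
    "a an the this that these those each every some any no both all several most".split()
)
_PREPOSITIONS = frozenset(
    "in on at of for with without by from into during against among between after "
    "before over under within than as via per throughout".split()
)
_CONJUNCTIONS = frozenset("and or but nor".split())
_PRONOUNS = frozenset("it they he she we you i its their his her our your them who which".split())
_MODALS = frozenset("may might can could will would shall should must".split())
_VERBS = frozenset(
    "is are was were be been being am has have had do does did appear appears appeared "
    "seem seems seemed remain remains remained show shows showed shown reduce reduces "
    "reduced treat treats treated prevent prevents prevented cause causes caused "
    "improve improves improved increase increases increased decrease decreases "
    "decreased find found trigger triggers triggered stop stops stopped observe "
    "observed report reported compare compared use used administer administered "
    "receive received suggest suggests suggested indicate indicates indicated include "
    "includes included confirm confirmed induce induced complicate complicates "
    "complicated diagnose diagnosed relieve relieves relieved lead leads led measure "
    "measured study studied return returned perform performed occur occurs occurred".split()
)
_ADJECTIVES = frozenset(
    "major minor severe acute chronic mild effective best common rare significant "
    "susceptible clinical oral intravenous new high low cardiovascular vasomotor "
    "frequent recurrent".split()
)
_NUMBER_RE = re.compile(r"\d+(?:[.,]\d+)*")
_ADJ_SUFFIXES = ("ous", "ive", "ible", "able", "ic", "ful", "ary", "al")


class HeuristicPOSTagger:
    """Closed-class word lists + suffix heuristics; everything else is a noun.

    A deliberately small shallow tagger: it only needs to separate nouns
    and pre-nominal adjectives/determiners from verbs, modals and function
    words well enough for base-NP chunking.
    """

    def tag(self, tokens: Sequence[Token]) -> list[Token]:
        return [replace(t, pos_tag=self._tag_word(t.text)) for t in tokens]

    @staticmethod
    def _tag_word(word: str) -> str:
        if not any(ch.isalnum() for ch in word):
            return "PUNCT"
        low = word.lower()
        if _NUMBER_RE.fullmatch(word):
            return "CD"
        if low == "to":
            return "TO"
        if low in _DETERMINERS:
            return "DT"
        if low in _PREPOSITIONS:
            return "IN"
        if low in _CONJUNCTIONS:
            return "CC"
        if low in _PRONOUNS:
            return "PRP"
        if low in _MODALS:
            return "MD"
        if low in _VERBS:
            return "VB"
        if low in _ADJECTIVES:
            return "JJ"
        if len(low) >= 4 and low.endswith("ly"):
            return "RB"
        if len(low) >= 5 and low.endswith("ed"):
            return "VB"
        if len(low) >= 5 and low.endswith(_ADJ_SUFFIXES):
            return "JJ"
        return "NN"


def chunk_noun_phrases(tokens: Sequence[Token]) -> list[PhraseSpan]:
    """Extract maximal base noun phrases: ``DT? JJ* NN+``.

    Noun-noun compounds are absorbed by the ``NN+`` tail; chunks never
    overlap and never split a (hyphenated) token.  Tokens must carry POS
    tags from a tagger.
    """
    tags = []
    for t in tokens:
        if t.pos_tag is None:
            raise ValueError("chunk_noun_phrases requires POS-tagged tokens")
        tags.append(t.pos_tag)
    chunks: list[PhraseSpan] = []
    i, n = 0, len(tokens)
    while i < n:
        j = i
        if j < n and tags[j] == "DT":
            j += 1
        while j < n and tags[j] == "JJ":
            j += 1
        if j < n and tags[j] == "NN":
            while j < n and tags[j] == "NN":
                j += 1
            toks = tuple(tokens[i:j])
            text = _phrase_text(toks)
            chunks.append(
                PhraseSpan(start=toks[0].start, end=toks[-1].end, text=text, tokens=toks)
            )
            i = j
        else:
            i += 1
    return chunks


def _phrase_text(toks: Sequence[Token]) -> str:
    parts = []
    prev_end = None
    for t in toks:
        if prev_end is not None:
            parts.append(" " * (t.start - prev_end))
        parts.append(t.text)
        prev_end = t.end
    return "".join(parts)
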