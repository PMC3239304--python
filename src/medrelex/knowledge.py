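"""Domain knowledge: lexicon, semantic schema, stoplist and seed pairs.

The lexicon is a term -> concept dictionary (a desk-scale stand-in for a
large medical metathesaurus): every concept carries one or more semantic
types ("Disease or Syndrome", "Pharmacologic Substance", ...), surface
variants are explicit term entries (``amoxicillin = amoxycillin = AMOX``),
and a stoplist bars noisy general words ("best", "normal", "take",
"reduce") from becoming entities.

The semantic schema groups semantic types into the coarse categories
Problem / Treatment / Test / Other and licenses, per directed (source
type, target type) pair, the ordered list of relations that may hold
between mentions of those types.  Six relations are modelled: treats,
prevents, causes, complicates, diagnoses and sign_or_symptom_of; each has
a global rank that fixes the order in which candidate relations are tried
during extraction.
"""

from __future__ import annotations

import dataclasses
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .segmentation import Token, tokenize

__all__ = [
    "Category",
    "Concept",
    "KnowledgeError",
    "Lexicon",
    "RELATION_NAMES",
    "DEFAULT_RELATION_RANKS",
    "SeedPair",
    "SemanticSchema",
    "SemanticType",
    "TermEntry",
    "TermMatch",
    "UnknownTypeError",
    "allowed_relations",
    "category_of",
    "load_lexicon",
    "load_schema",
    "load_seed_pairs",
    "lookup",
    "normalize_term",
    "save_lexicon",
    "term_key",
]


class KnowledgeError(ValueError):
    """Raised for malformed or inconsistent knowledge resources."""


class UnknownTypeError(KnowledgeError):
    """Raised when a semantic type name is not declared in the schema."""


class Category(str, Enum):
    """Coarse entity category a semantic type belongs to."""

    PROBLEM = "Problem"
    TREATMENT = "Treatment"
    TEST = "Test"
    OTHER = "Other"


#: The six relation names handled by the pipeline.
RELATION_NAMES: tuple[str, ...] = (
    "treats",
    "prevents",
    "causes",
    "complicates",
    "diagnoses",
    "sign_or_symptom_of",
)

#: Default trial order of candidate relations (lower rank = tried first).
#: The order is an empirical tuning knob and can be overridden in the
#: schema file; treats leads because it is the pipeline's headline relation.
DEFAULT_RELATION_RANKS: dict[str, int] = {
    "treats": 1,
    "prevents": 2,
    "diagnoses": 3,
    "causes": 4,
    "sign_or_symptom_of": 5,
    "complicates": 6,
}

_WS_RE = re.compile(r"\s+")


def normalize_term(surface: str) -> str:
    """Normalize a surface form for dictionary lookup.

    Lowercase, Unicode NFC, internal whitespace collapsed to single
    spaces, outer whitespace stripped.  Idempotent.
    """
    return _WS_RE.sub(" ", unicodedata.normalize("NFC", surface).lower()).strip()


def term_key(surface: str) -> str:
    """Canonical index key for a term: tokenization-aware normalization.

    Tokenizing before joining makes multiword keys insensitive to
    punctuation spacing ("Rhinitis, Vasomotor" and "rhinitis , vasomotor"
    index identically), which keeps phrase lookup consistent with the
    sentence tokenizer.
    """
    return normalize_term(" ".join(t.text for t in tokenize(surface)))


@dataclass(frozen=True)
class SemanticType:
    name: str
    category: Category


@dataclass(frozen=True)
class Concept:
    """A dictionary concept with a CUI-like opaque identifier."""

    id: str
    preferred_name: str
    semantic_types: tuple[str, ...]


@dataclass(frozen=True)
class TermEntry:
    surface: str
    concept_id: str
    normalized: str


@dataclass(frozen=True)
class SeedPair:
    """A concept pair known (from a knowledge base) to stand in a relation."""

    concept1_id: str
    relation: str
    concept2_id: str


@dataclass(frozen=True)
class TermMatch:
    """A dictionary hit inside a tokenized phrase."""

    token_start: int
    token_end: int
    start: int  # character offset of the first matched token
    end: int  # character offset past the last matched token
    key: str
    concept_ids: tuple[str, ...]


class SemanticSchema:
    """Semantic types, their categories, and licensed relations per type pair."""

    def __init__(
        self,
        types: Iterable[SemanticType],
        licensed: dict[tuple[str, str], Sequence[str]],
        relation_ranks: dict[str, int] | None = None,
    ) -> None:
        self.types: dict[str, SemanticType] = {}
        for st in types:
            if st.name in self.types:
                raise KnowledgeError(f"duplicate semantic type {st.name!r}")
            self.types[st.name] = st
        ranks = dict(relation_ranks or DEFAULT_RELATION_RANKS)
        if set(ranks) != set(RELATION_NAMES):
            missing = set(RELATION_NAMES) - set(ranks)
            extra = set(ranks) - set(RELATION_NAMES)
            raise KnowledgeError(
                f"relation ranks must cover exactly the six relations "
                f"(missing {sorted(missing)}, unknown {sorted(extra)})"
            )
        if sorted(ranks.values()) != list(range(1, len(RELATION_NAMES) + 1)):
            raise KnowledgeError("relation ranks must be a permutation of 1..6")
        self.relation_ranks: dict[str, int] = ranks
        self.licensed: dict[tuple[str, str], tuple[str, ...]] = {}
        for (src, tgt), rels in licensed.items():
            for name in (src, tgt):
                if name not in self.types:
                    raise UnknownTypeError(f"unknown semantic type {name!r} in licensed pair")
            rels = list(rels)
            if len(set(rels)) != len(rels):
                raise KnowledgeError(f"duplicate relation in licensed list for ({src}, {tgt})")
            for r in rels:
                if r not in ranks:
                    raise KnowledgeError(f"unknown relation {r!r} for ({src}, {tgt})")
            self.licensed[(src, tgt)] = tuple(sorted(rels, key=ranks.__getitem__))

    def type_names(self) -> list[str]:
        return sorted(self.types)


def category_of(schema: SemanticSchema, type_name: str) -> Category:
    """Return the declared category of a semantic type."""
    try:
        return schema.types[type_name].category
    except KeyError:
        raise UnknownTypeError(f"unknown semantic type {type_name!r}") from None


def allowed_relations(schema: SemanticSchema, source_type: str, target_type: str) -> list[str]:
    """Licensed relations for a directed (source, target) type pair.

    Sorted by relation rank ascending; empty if the pair is unlicensed.
    Direction matters: ``(A, B)`` and ``(B, A)`` are distinct keys.
    """
    for name in (source_type, target_type):
        if name not in schema.types:
            raise UnknownTypeError(f"unknown semantic type {name!r}")
    rels = schema.licensed.get((source_type, target_type), ())
    return sorted(rels, key=schema.relation_ranks.__getitem__)


class Lexicon:
    """Concepts, surface-term index and stoplist.

    A surface form may simultaneously be a term and a stoplist entry
    (dictionary noise such as "normal" genuinely occurs in medical
    vocabularies); the stoplist wins at filter time, not at lookup time.
    """

    def __init__(
        self,
        concepts: Iterable[Concept] = (),
        terms: Iterable[TermEntry] = (),
        stoplist: Iterable[str] = (),
    ) -> None:
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self.concepts:
                raise KnowledgeError(f"duplicate concept id {c.id!r}")
            self.concepts[c.id] = c
        self.terms: list[TermEntry] = []
        self.term_index: dict[str, list[str]] = {}
        self.stoplist: set[str] = {normalize_term(s) for s in stoplist}
        self._max_term_tokens = 0
        for t in terms:
            self.add_term(t.surface, t.concept_id)

    def add_term(self, surface: str, concept_id: str) -> None:
        if concept_id not in self.concepts:
            raise KnowledgeError(f"term {surface!r} references unknown concept {concept_id!r}")
        key = term_key(surface)
        if not key:
            raise KnowledgeError(f"empty term surface for concept {concept_id!r}")
        self.terms.append(TermEntry(surface=surface, concept_id=concept_id, normalized=key))
        ids = self.term_index.setdefault(key, [])
        if concept_id not in ids:
            ids.append(concept_id)
        self._max_term_tokens = max(self._max_term_tokens, len(key.split(" ")))

    @property
    def max_term_tokens(self) -> int:
        return self._max_term_tokens

    def surfaces_for(self, concept_id: str) -> list[str]:
        return [t.surface for t in self.terms if t.concept_id == concept_id]

    def ambiguous(self, key: str) -> bool:
        """True if the normalized key maps to more than one concept."""
        return len(self.term_index.get(key, [])) > 1


def lookup(lexicon: Lexicon, phrase: Union[str, Sequence[Token]]) -> list[TermMatch]:
    """Greedy left-to-right longest-match dictionary lookup inside a phrase.

    At each start position the longest matching lexicon term wins; matches
    never overlap.  Each match carries every candidate concept id for the
    matched term (sorted for determinism).  Unknown phrases yield ``[]``.
    """
    toks: list[Token] = list(tokenize(phrase)) if isinstance(phrase, str) else list(phrase)
    out: list[TermMatch] = []
    n = len(toks)
    i = 0
    while i < n:
        hit = None
        for j in range(min(lexicon.max_term_tokens, n - i), 0, -1):
            key = normalize_term(" ".join(t.text for t in toks[i : i + j]))
            ids = lexicon.term_index.get(key)
            if ids:
                hit = TermMatch(
                    token_start=i,
                    token_end=i + j,
                    start=toks[i].start,
                    end=toks[i + j - 1].end,
                    key=key,
                    concept_ids=tuple(sorted(ids)),
                )
                break
        if hit is not None:
            out.append(hit)
            i = hit.token_end
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# File formats (YAML for lexicon/schema, TSV for seed pairs)
# ---------------------------------------------------------------------------


def _require(entry: dict, key: str, where: str):
    if not isinstance(entry, dict) or key not in entry:
        raise KnowledgeError(f"{where}: missing field {key!r}")
    return entry[key]


def load_schema(path: Union[str, Path]) -> SemanticSchema:
    """Load a semantic schema from YAML.

    Layout::

        types:     [{name, category}, ...]
        relations: [{name, rank}, ...]          # optional; defaults shipped
        licensed:  [{source, target, relations: [..]}, ...]
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    types = []
    for i, entry in enumerate(data.get("types") or []):
        name = _require(entry, "name", f"types[{i}]")
        cat = _require(entry, "category", f"types[{i}]")
        try:
            category = Category(cat)
        except ValueError:
            raise KnowledgeError(f"types[{i}]: unknown category {cat!r}") from None
        types.append(SemanticType(name=str(name), category=category))
    ranks = None
    if data.get("relations"):
        ranks = {}
        for i, entry in enumerate(data["relations"]):
            ranks[str(_require(entry, "name", f"relations[{i}]"))] = int(
                _require(entry, "rank", f"relations[{i}]")
            )
    licensed: dict[tuple[str, str], list[str]] = {}
    for i, entry in enumerate(data.get("licensed") or []):
        src = str(_require(entry, "source", f"licensed[{i}]"))
        tgt = str(_require(entry, "target", f"licensed[{i}]"))
        rels = _require(entry, "relations", f"licensed[{i}]")
        if (src, tgt) in licensed:
            raise KnowledgeError(f"licensed[{i}]: duplicate pair ({src}, {tgt})")
        licensed[(src, tgt)] = [str(r) for r in rels]
    return SemanticSchema(types, licensed, ranks)


def load_lexicon(
    path: Union[str, Path],
    schema: SemanticSchema,
    extra_stoplist: Iterable[str] = (),
) -> Lexicon:
    """Load a lexicon from YAML and validate it against the schema.

    Layout::

        concepts: [{id, preferred_name, semantic_types: [..]}, ...]
        terms:    [{surface, concept_id}, ...]
        stoplist: [word, ...]

    Each concept's preferred name is indexed as a term automatically;
    ``terms`` entries add surface variants.  Semantic types must exist in
    the schema (the offending name is reported otherwise).
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    concepts = []
    for i, entry in enumerate(data.get("concepts") or []):
        cid = str(_require(entry, "id", f"concepts[{i}]"))
        name = str(_require(entry, "preferred_name", f"concepts[{i}]"))
        stypes = _require(entry, "semantic_types", f"concepts[{i}]")
        if not stypes:
            raise KnowledgeError(f"concepts[{i}] ({cid}): semantic_types must be non-empty")
        for st in stypes:
            if st not in schema.types:
                raise UnknownTypeError(
                    f"concepts[{i}] ({cid}): unknown semantic type {st!r}"
                )
        concepts.append(
            Concept(id=cid, preferred_name=name, semantic_types=tuple(str(s) for s in stypes))
        )
    lex = Lexicon(concepts=concepts, stoplist=data.get("stoplist") or [])
    for c in concepts:
        lex.add_term(c.preferred_name, c.id)
    for i, entry in enumerate(data.get("terms") or []):
        surface = str(_require(entry, "surface", f"terms[{i}]"))
        cid = str(_require(entry, "concept_id", f"terms[{i}]"))
        lex.add_term(surface, cid)
    for word in extra_stoplist:
        lex.stoplist.add(normalize_term(word))
    return lex


def save_lexicon(lexicon: Lexicon, path: Union[str, Path]) -> None:
    """Serialize a lexicon back to the YAML dialect read by load_lexicon."""
    preferred = {c.id: term_key(c.preferred_name) for c in lexicon.concepts.values()}
    data = {
        "concepts": [
            {
                "id": c.id,
                "preferred_name": c.preferred_name,
                "semantic_types": list(c.semantic_types),
            }
            for c in lexicon.concepts.values()
        ],
        # preferred names are re-indexed automatically on load
        "terms": [
            {"surface": t.surface, "concept_id": t.concept_id}
            for t in lexicon.terms
            if t.normalized != preferred.get(t.concept_id)
        ],
        "stoplist": sorted(lexicon.stoplist),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def load_seed_pairs(path: Union[str, Path], lexicon: Lexicon) -> list[SeedPair]:
    """Load seed pairs from TSV: ``concept1_id<TAB>relation<TAB>concept2_id``."""
    seeds: list[SeedPair] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise KnowledgeError(f"line {lineno}: expected 3 tab-separated fields")
            c1, rel, c2 = parts
            if rel not in RELATION_NAMES:
                raise KnowledgeError(f"line {lineno}: unknown relation {rel!r}")
            for cid in (c1, c2):
                if cid not in lexicon.concepts:
                    raise KnowledgeError(f"line {lineno}: unknown concept id {cid!r}")
            seeds.append(SeedPair(concept1_id=c1, relation=rel, concept2_id=c2))
    return seeds
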