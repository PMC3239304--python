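"""Typed linguistic patterns and relation-triple extraction.

Pattern dialect
---------------
A template is a whitespace-separated sequence of

* literal tokens (matched case-insensitively by default),
* one ``E1`` and one ``E2`` slot, optionally category-constrained as
  ``E1[Treatment]``; bare slots take per-relation defaults,
* ``(...)?`` optional groups and ``(a|b)`` alternation groups,
* ``...`` — a bounded gap of 0..6 arbitrary non-slot tokens.

Every pattern has a *specialization degree* — the number of obligatory
literal tokens — and patterns of the same relation are tried most-specific
first.  Candidate relations for a mention pair come from the schema
(licensed relations per directed type pair) and are tried in the global
relation rank order; by default the first successful match decides the
pair ("one relation per pair").

Coordinated noun phrases are handled at match time: when mentions of the
same category are separated only by ``,``/``and``/``or``, a slot aligned
with any one of them consumes the whole coordination group, so the
sentence "Fosfomycin and amoxicillin-clavulanate appear to be effective
for cystitis ..." yields one treats triple per coordinated treatment.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .knowledge import (
    Category,
    RELATION_NAMES,
    SemanticSchema,
    allowed_relations,
)
from .ner import EntityMention, mention_from_dict, mention_to_dict
from .segmentation import SentenceSpan, Token, tokenize

__all__ = [
    "CompiledPattern",
    "DEFAULT_GAP_MAX",
    "DEFAULT_SLOT_CATEGORIES",
    "ExtractionConfig",
    "Gap",
    "Group",
    "Lit",
    "PatternError",
    "PatternSpec",
    "RelationTriple",
    "Slot",
    "compile_pattern",
    "compile_patterns",
    "extract",
    "load_pattern_specs",
    "match",
    "parse_template",
    "save_pattern_specs",
    "specialization_degree",
    "triple_from_dict",
    "triple_to_dict",
]

DEFAULT_GAP_MAX = 6

#: Default (E1, E2) category constraints when a template uses bare slots.
DEFAULT_SLOT_CATEGORIES: dict[str, tuple[str, str]] = {
    "treats": ("Treatment", "Problem"),
    "prevents": ("Treatment", "Problem"),
    "diagnoses": ("Test", "Problem"),
    "causes": ("Problem", "Problem"),
    "complicates": ("Problem", "Problem"),
    "sign_or_symptom_of": ("Problem", "Problem"),
}


class PatternError(ValueError):
    """Template syntax or semantics error, with character position."""

    def __init__(self, message: str, pos: int = 0):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


# --- template AST -----------------------------------------------------------


@dataclass(frozen=True)
class Lit:
    text: str


@dataclass(frozen=True)
class Gap:
    pass


@dataclass(frozen=True)
class Slot:
    index: int  # 1 or 2
    category: str | None = None


@dataclass(frozen=True)
class Group:
    alternatives: tuple[tuple, ...]
    optional: bool


Node = Union[Lit, Gap, Slot, Group]

_SLOT_RE = re.compile(r"^E([12])(?:\[([^\]]*)\])?$")


def parse_template(template: str) -> tuple[Node, ...]:
    """Parse a template into its AST, validating slot usage."""
    nodes, i = _parse_seq(template, 0)
    if i != len(template):
        raise PatternError("unexpected ')'", i)
    counts = {1: 0, 2: 0}

    def walk(ns: Sequence[Node], in_group: bool) -> None:
        for n in ns:
            if isinstance(n, Slot):
                if in_group:
                    raise PatternError("slots are not allowed inside groups")
                counts[n.index] += 1
            elif isinstance(n, Group):
                for alt in n.alternatives:
                    walk(alt, True)

    walk(nodes, False)
    if counts[1] != 1 or counts[2] != 1:
        raise PatternError(
            f"template must contain exactly one E1 and one E2 slot "
            f"(found {counts[1]} E1, {counts[2]} E2)"
        )
    return tuple(nodes)


def _parse_seq(s: str, i: int) -> tuple[list[Node], int]:
    nodes: list[Node] = []
    n = len(s)
    while i < n:
        if s[i].isspace():
            i += 1
            continue
        c = s[i]
        if c in ")|":
            break
        if c == "(":
            start = i
            i += 1
            alts: list[tuple] = []
            seq, i = _parse_seq(s, i)
            alts.append(tuple(seq))
            while i < n and s[i] == "|":
                i += 1
                seq, i = _parse_seq(s, i)
                alts.append(tuple(seq))
            if i >= n or s[i] != ")":
                raise PatternError("unclosed group", start)
            i += 1
            optional = i < n and s[i] == "?"
            if optional:
                i += 1
            nodes.append(Group(alternatives=tuple(alts), optional=optional))
            continue
        j = i
        while j < n and not s[j].isspace() and s[j] not in "()|":
            j += 1
        word = s[i:j]
        if word == "...":
            nodes.append(Gap())
        else:
            m = _SLOT_RE.match(word)
            if m:
                nodes.append(Slot(index=int(m.group(1)), category=m.group(2)))
            else:
                nodes.append(Lit(word))
        i = j
    return nodes, i


def specialization_degree(template: Union[str, Sequence[Node]]) -> int:
    """Count of obligatory literal tokens.

    Optional groups contribute nothing; a mandatory alternation group
    contributes the minimum over its branches; slots and gaps never count.
    """
    nodes = parse_template(template) if isinstance(template, str) else template
    total = 0
    for n in nodes:
        if isinstance(n, Lit):
            total += 1
        elif isinstance(n, Group) and not n.optional:
            total += min(specialization_degree(alt) for alt in n.alternatives)
    return total


# --- compiled form ----------------------------------------------------------


@dataclass(frozen=True)
class PatternSpec:
    pattern_id: str
    relation: str
    template: str
    declared_degree: int | None = None
    status: str | None = None  # None/"accepted" usable; "candidate"/"rejected" not


@dataclass(frozen=True)
class CompiledPattern:
    pattern_id: str
    relation: str
    source_category: str
    target_category: str
    degree: int
    regex: str
    nodes: tuple[Node, ...]
    gap_max: int = DEFAULT_GAP_MAX


_E1 = "\ue001"  # private-use sentinel standing for the E1 slot filler
_E2 = "\ue002"  # sentinel for the E2 slot filler


def _nodes_regex(nodes: Sequence[Node], gap_max: int) -> str:
    parts: list[str] = []
    for n in nodes:
        if isinstance(n, Lit):
            parts.append(" " + re.escape(n.text))
        elif isinstance(n, Slot):
            parts.append(" " + (_E1 if n.index == 1 else _E2))
        elif isinstance(n, Gap):
            parts.append(f"(?: [^{_E1}{_E2} ]+){{0,{gap_max}}}")
        else:  # Group
            inner = "|".join(_nodes_regex(alt, gap_max) for alt in n.alternatives)
            parts.append(f"(?:{inner})" + ("?" if n.optional else ""))
    return "".join(parts)


def compile_pattern(
    spec: PatternSpec,
    schema: SemanticSchema | None = None,
    slot_categories: dict[str, tuple[str, str]] | None = None,
    gap_max: int = DEFAULT_GAP_MAX,
) -> CompiledPattern:
    """Compile a pattern spec, binding slot categories and the degree."""
    if spec.relation not in RELATION_NAMES:
        raise PatternError(f"unknown relation {spec.relation!r}")
    nodes = parse_template(spec.template)
    defaults = (slot_categories or DEFAULT_SLOT_CATEGORIES)[spec.relation]
    cats = {1: defaults[0], 2: defaults[1]}
    for n in nodes:
        if isinstance(n, Slot) and n.category is not None:
            if n.category not in Category._value2member_map_:
                raise PatternError(f"unknown category {n.category!r}")
            cats[n.index] = n.category
    degree = spec.declared_degree if spec.declared_degree is not None else specialization_degree(nodes)
    return CompiledPattern(
        pattern_id=spec.pattern_id,
        relation=spec.relation,
        source_category=cats[1],
        target_category=cats[2],
        degree=degree,
        regex=_nodes_regex(nodes, gap_max),
        nodes=nodes,
        gap_max=gap_max,
    )


def compile_patterns(
    specs: Iterable[PatternSpec],
    schema: SemanticSchema | None = None,
    **kwargs,
) -> list[CompiledPattern]:
    """Compile every usable spec (status missing or 'accepted')."""
    return [
        compile_pattern(s, schema, **kwargs)
        for s in specs
        if s.status in (None, "accepted")
    ]


@functools.lru_cache(maxsize=1024)
def _compiled_regex(regex: str, flags: int) -> re.Pattern:
    return re.compile(regex, flags)


# --- matching ---------------------------------------------------------------

_COORD_TOKENS = frozenset({",", "and", "or"})


def _coordination_span(
    mention: EntityMention,
    mentions: Sequence[EntityMention] | None,
    tokens: Sequence[Token],
) -> tuple[int, int]:
    """Character span of the coordination group containing ``mention``.

    Same-category mentions count as coordinated when every token strictly
    between consecutive mention spans is a comma, "and" or "or".
    """
    if not mentions:
        return (mention.start, mention.end)
    same = sorted(
        {(m.start, m.end) for m in mentions if m.category == mention.category},
    )
    try:
        pos = same.index((mention.start, mention.end))
    except ValueError:
        return (mention.start, mention.end)

    def linked(a: tuple[int, int], b: tuple[int, int]) -> bool:
        between = [t for t in tokens if a[1] <= t.start and t.end <= b[0]]
        return all(t.text.lower() in _COORD_TOKENS for t in between) and b[0] >= a[1]

    lo = pos
    while lo > 0 and linked(same[lo - 1], same[lo]):
        lo -= 1
    hi = pos
    while hi + 1 < len(same) and linked(same[hi], same[hi + 1]):
        hi += 1
    return (same[lo][0], same[hi][1])


def match(
    pattern: CompiledPattern,
    tokens: Sequence[Token],
    e1: EntityMention,
    e2: EntityMention,
    mentions: Sequence[EntityMention] | None = None,
    case_sensitive: bool = False,
) -> bool:
    """True iff the token sequence instantiates the template for (e1, e2).

    Category constraints are checked before any textual matching; entity
    spans (expanded to their coordination groups) act as atomic slot
    fillers; matching never looks outside the provided tokens.
    """
    if e1.category != pattern.source_category or e2.category != pattern.target_category:
        return False
    g1 = _coordination_span(e1, mentions, tokens)
    g2 = _coordination_span(e2, mentions, tokens)
    if g1[0] < g2[1] and g2[0] < g1[1]:  # groups overlap: fall back to bare spans
        g1, g2 = (e1.start, e1.end), (e2.start, e2.end)
        if g1[0] < g2[1] and g2[0] < g1[1]:
            return False
    elems: list[str] = []
    placed1 = placed2 = False
    for t in tokens:
        if g1[0] <= t.start and t.end <= g1[1]:
            if not placed1:
                elems.append(_E1)
                placed1 = True
        elif g2[0] <= t.start and t.end <= g2[1]:
            if not placed2:
                elems.append(_E2)
                placed2 = True
        else:
            elems.append(t.text)
    if not (placed1 and placed2):
        return False
    seq = " " + " ".join(elems)
    flags = 0 if case_sensitive else re.IGNORECASE
    return _compiled_regex(pattern.regex, flags).search(seq) is not None


# --- extraction -------------------------------------------------------------


@dataclass(frozen=True)
class RelationTriple:
    """<source mention, relation, target mention> with provenance."""

    source: EntityMention
    relation: str
    target: EntityMention
    pattern_id: str = ""

    @property
    def doc_id(self) -> str:
        return self.source.doc_id


@dataclass(frozen=True)
class ExtractionConfig:
    one_relation_per_pair: bool = True
    case_sensitive: bool = False


def extract(
    sentence: Union[str, SentenceSpan, None],
    mentions: Sequence[EntityMention],
    patterns: Sequence[CompiledPattern],
    schema: SemanticSchema,
    config: ExtractionConfig | None = None,
    tokens: Sequence[Token] | None = None,
) -> list[RelationTriple]:
    """Extract relation triples from one sentence.

    For every ordered mention pair (a, b) the schema-licensed candidate
    relations are tried in rank order; within a relation, patterns are
    tried by degree descending (pattern id breaks ties).  The first
    successful match emits a triple and — with ``one_relation_per_pair``
    — closes the pair.  Pairs are independent, so one sentence may yield
    several triples.  Output is deterministic and independent of the
    order patterns were supplied in.
    """
    cfg = config or ExtractionConfig()
    if tokens is None:
        if sentence is None:
            raise ValueError("either sentence or tokens must be provided")
        tokens = tokenize(sentence)
    by_rel: dict[str, list[CompiledPattern]] = {}
    for p in sorted(patterns, key=lambda p: (-p.degree, p.pattern_id)):
        by_rel.setdefault(p.relation, []).append(p)
    ms = sorted(mentions, key=lambda m: (m.start, m.end, m.concept_id))
    triples: list[RelationTriple] = []
    for a in ms:
        for b in ms:
            if a is b or (a.start, a.end) == (b.start, b.end):
                continue
            for rel in allowed_relations(schema, a.semantic_type, b.semantic_type):
                emitted = False
                for p in by_rel.get(rel, ()):
                    if match(p, tokens, a, b, mentions=ms, case_sensitive=cfg.case_sensitive):
                        triples.append(
                            RelationTriple(source=a, relation=rel, target=b, pattern_id=p.pattern_id)
                        )
                        emitted = True
                        break
                if emitted and cfg.one_relation_per_pair:
                    break
    return triples


# --- pattern files and JSON -------------------------------------------------


def load_pattern_specs(path: Union[str, Path]) -> list[PatternSpec]:
    """Read a YAML pattern file: a list of {id, relation, template, degree?, status?}."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or []
    specs = []
    for i, entry in enumerate(data):
        for key in ("id", "relation", "template"):
            if key not in entry:
                raise PatternError(f"patterns[{i}]: missing field {key!r}")
        specs.append(
            PatternSpec(
                pattern_id=str(entry["id"]),
                relation=str(entry["relation"]),
                template=str(entry["template"]),
                declared_degree=entry.get("degree"),
                status=entry.get("status"),
            )
        )
    return specs


def save_pattern_specs(specs: Iterable[PatternSpec], path: Union[str, Path]) -> None:
    data = []
    for s in specs:
        entry = {"id": s.pattern_id, "relation": s.relation, "template": s.template}
        if s.declared_degree is not None:
            entry["degree"] = s.declared_degree
        if s.status is not None:
            entry["status"] = s.status
        data.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def triple_to_dict(t: RelationTriple) -> dict:
    return {
        "doc_id": t.doc_id,
        "relation": t.relation,
        "pattern_id": t.pattern_id,
        "source": mention_to_dict(t.source),
        "target": mention_to_dict(t.target),
    }


def triple_from_dict(d: dict) -> RelationTriple:
    return RelationTriple(
        source=mention_from_dict(d["source"]),
        relation=d["relation"],
        target=mention_from_dict(d["target"]),
        pattern_id=d.get("pattern_id", ""),
    )
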