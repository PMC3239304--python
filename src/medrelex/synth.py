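"""Synthetic fixture corpora with exact gold annotations.

The generator instantiates relation-pattern templates with lexicon terms
to produce positive sentences whose gold mentions and triples are known
by construction, plus three families of distractors that reproduce the
classic false-positive causes of pattern-based extraction:

* co-occurrence distractors — two licensed entities in one sentence with
  neutral wording that asserts no relation;
* other-relation distractors — the wording of some relation instantiated
  with a type pair that does not license it;
* stoplist traps — sentences containing a dictionary term that is also a
  stoplist word (dictionary noise such as "normal").

A separate perturbation step injects controlled boundary and type errors
into gold mentions so the boundary-weighted evaluation metrics can be
exercised at exact, configured error rates.

Generation is a pure function of (lexicon, patterns, schema, config):
the same seed reproduces a byte-identical corpus.  The filler vocabulary
is disjoint from the lexicon, so no accidental mentions arise; fixtures
are structural stand-ins, not imitations of real prose.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from typing import Sequence

from .knowledge import Lexicon, SemanticSchema, category_of, term_key
from .ner import EntityMention
from .relations import CompiledPattern, Gap, Group, Lit, RelationTriple, Slot
from .segmentation import Document

__all__ = [
    "FILLER_WORDS",
    "GenConfig",
    "GenerationError",
    "PerturbConfig",
    "SyntheticCorpus",
    "generate",
    "perturb",
]

#: Neutral gap/context vocabulary; must never collide with lexicon terms.
FILLER_WORDS: tuple[str, ...] = (
    "notably",
    "reportedly",
    "consistently",
    "furthermore",
    "apparently",
    "generally",
)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class GenConfig:
    n_positive: int = 10
    n_distractor_cooccur: int = 0
    n_distractor_otherrel: int = 0
    n_stoplist_traps: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "n_positive",
            "n_distractor_cooccur",
            "n_distractor_otherrel",
            "n_stoplist_traps",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PerturbConfig:
    boundary_error_rate: float = 0.0
    type_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("boundary_error_rate", "type_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.boundary_error_rate + self.type_error_rate > 1.0 + 1e-12:
            raise ValueError("error rates must sum to at most 1")


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    gold_mentions: list[EntityMention]
    gold_triples: list[RelationTriple]

    def document_by_id(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


# --- term candidates --------------------------------------------------------


def _term_candidates(lexicon: Lexicon, schema: SemanticSchema) -> dict[str, list[tuple[str, str]]]:
    """Per semantic type: (concept_id, surface) choices safe for generation.

    Safe means the recognition pipeline will recover exactly the planted
    mention: the concept is single-typed, the surface maps to only that
    concept, and the surface is not stoplisted.
    """
    out: dict[str, list[tuple[str, str]]] = {}
    for entry in lexicon.terms:
        concept = lexicon.concepts[entry.concept_id]
        if len(concept.semantic_types) != 1:
            continue
        if lexicon.ambiguous(entry.normalized) or entry.normalized in lexicon.stoplist:
            continue
        stype = concept.semantic_types[0]
        surface = " ".join(entry.surface.split())
        item = (entry.concept_id, surface)
        bucket = out.setdefault(stype, [])
        if item not in bucket:
            bucket.append(item)
    for bucket in out.values():
        bucket.sort()
    return out


def _licensed_pairs_for(
    pattern: CompiledPattern,
    schema: SemanticSchema,
    cands: dict[str, list[tuple[str, str]]],
) -> list[tuple[str, str]]:
    pairs = []
    for (t1, t2), rels in sorted(schema.licensed.items()):
        if (
            pattern.relation in rels
            and category_of(schema, t1).value == pattern.source_category
            and category_of(schema, t2).value == pattern.target_category
            and cands.get(t1)
            and cands.get(t2)
        ):
            pairs.append((t1, t2))
    return pairs


def _unlicensed_pairs_for(
    pattern: CompiledPattern,
    schema: SemanticSchema,
    cands: dict[str, list[tuple[str, str]]],
) -> list[tuple[str, str]]:
    """Category-compatible type pairs licensing *no* relation at all."""
    pairs = []
    for t1 in sorted(cands):
        if category_of(schema, t1).value != pattern.source_category:
            continue
        for t2 in sorted(cands):
            if t1 == t2 or category_of(schema, t2).value != pattern.target_category:
                continue
            if not schema.licensed.get((t1, t2)):
                pairs.append((t1, t2))
    return pairs


# --- sentence assembly ------------------------------------------------------


def _realize(pattern: CompiledPattern, rng: random.Random) -> list[tuple[str, object]]:
    """Expand a template AST into ("tok", text) / ("slot", index) items."""

    def walk(nodes) -> list[tuple[str, object]]:
        items: list[tuple[str, object]] = []
        for n in nodes:
            if isinstance(n, Lit):
                items.append(("tok", n.text))
            elif isinstance(n, Slot):
                items.append(("slot", n.index))
            elif isinstance(n, Gap):
                for _ in range(rng.randint(0, 2)):
                    items.append(("tok", rng.choice(FILLER_WORDS)))
            elif isinstance(n, Group):
                if n.optional and rng.random() < 0.5:
                    continue
                items.extend(walk(n.alternatives[rng.randrange(len(n.alternatives))]))
        return items

    return walk(pattern.nodes)


def _assemble(
    doc_id: str,
    items: Sequence[tuple[str, object]],
    slot_fillers: dict[int, tuple[str, str, str, str]],  # index -> (concept, surface, type, cat)
) -> tuple[Document, dict[int, EntityMention]]:
    words: list[str] = []
    spans: dict[int, tuple[int, int, str]] = {}
    pos = 0
    for kind, value in items:
        if kind == "tok":
            word = str(value)
        else:
            _, surface, _, _ = slot_fillers[int(value)]  # type: ignore[arg-type]
            word = surface
        start = pos
        words.append(word)
        pos += len(word)
        if kind == "slot":
            spans[int(value)] = (start, pos, word)  # type: ignore[arg-type]
        pos += 1  # joining space
    words.append(".")
    text = " ".join(words)
    mentions: dict[int, EntityMention] = {}
    for idx, (start, end, surface) in spans.items():
        concept_id, _, stype, cat = slot_fillers[idx]
        mentions[idx] = EntityMention(
            doc_id=doc_id,
            start=start,
            end=end,
            surface=surface,
            concept_id=concept_id,
            semantic_type=stype,
            category=cat,
            sent_start=0,
            sent_end=len(text),
        )
    return Document(doc_id=doc_id, text=text), mentions


def _pick_fillers(
    pair: tuple[str, str],
    pattern: CompiledPattern,
    cands: dict[str, list[tuple[str, str]]],
    rng: random.Random,
) -> dict[int, tuple[str, str, str, str]]:
    t1, t2 = pair
    c1 = rng.choice(cands[t1])
    choices2 = [c for c in cands[t2] if c[0] != c1[0]]
    if not choices2:
        raise GenerationError(f"no distinct term for type {t2!r}")
    c2 = rng.choice(choices2)
    return {
        1: (c1[0], c1[1], t1, pattern.source_category),
        2: (c2[0], c2[1], t2, pattern.target_category),
    }


# --- generation -------------------------------------------------------------


def generate(
    lexicon: Lexicon,
    patterns: Sequence[CompiledPattern],
    schema: SemanticSchema,
    config: GenConfig,
) -> SyntheticCorpus:
    """Generate documents (one sentence each) with exact gold annotations."""
    rng = random.Random(config.rng_seed)
    cands = _term_candidates(lexicon, schema)
    pats = sorted(patterns, key=lambda p: p.pattern_id)
    usable = [(p, _licensed_pairs_for(p, schema, cands)) for p in pats]
    usable = [(p, pairs) for p, pairs in usable if pairs]
    if config.n_positive > 0 and not usable:
        raise GenerationError("no pattern is instantiable with the given lexicon/schema")

    documents: list[Document] = []
    gold_mentions: list[EntityMention] = []
    gold_triples: list[RelationTriple] = []

    for i in range(config.n_positive):
        pattern, pairs = usable[rng.randrange(len(usable))]
        fillers = _pick_fillers(pairs[rng.randrange(len(pairs))], pattern, cands, rng)
        doc, mentions = _assemble(f"pos{i:04d}", _realize(pattern, rng), fillers)
        documents.append(doc)
        gold_mentions.extend(mentions[k] for k in sorted(mentions))
        gold_triples.append(
            RelationTriple(
                source=mentions[1],
                relation=pattern.relation,
                target=mentions[2],
                pattern_id=pattern.pattern_id,
            )
        )

    cooccur_words = "was studied alongside".split()
    tail_words = "in this cohort".split()
    licensed_any = sorted(
        (t1, t2)
        for (t1, t2), rels in schema.licensed.items()
        if rels and cands.get(t1) and cands.get(t2)
    )
    for i in range(config.n_distractor_cooccur):
        if not licensed_any:
            raise GenerationError("no licensed type pair with available terms")
        t1, t2 = licensed_any[rng.randrange(len(licensed_any))]
        fake = CompiledPattern(
            pattern_id="cooccur",
            relation="treats",
            source_category=category_of(schema, t1).value,
            target_category=category_of(schema, t2).value,
            degree=0,
            regex="",
            nodes=(),
        )
        fillers = _pick_fillers((t1, t2), fake, cands, rng)
        items = (
            [("slot", 1)]
            + [("tok", w) for w in cooccur_words]
            + [("slot", 2)]
            + [("tok", w) for w in tail_words]
        )
        doc, mentions = _assemble(f"codoc{i:04d}", items, fillers)
        documents.append(doc)
        gold_mentions.extend(mentions[k] for k in sorted(mentions))

    for i in range(config.n_distractor_otherrel):
        options = [
            (p, _unlicensed_pairs_for(p, schema, cands)) for p, _ in usable
        ]
        options = [(p, pairs) for p, pairs in options if pairs]
        if not options:
            raise GenerationError("no unlicensed type pair fits any pattern")
        pattern, pairs = options[rng.randrange(len(options))]
        fillers = _pick_fillers(pairs[rng.randrange(len(pairs))], pattern, cands, rng)
        doc, mentions = _assemble(f"alt{i:04d}", _realize(pattern, rng), fillers)
        documents.append(doc)
        gold_mentions.extend(mentions[k] for k in sorted(mentions))

    trap_keys = sorted(k for k in lexicon.term_index if k in lexicon.stoplist)
    trap_words = "values returned to".split()
    trap_tail = "within days".split()
    problem_types = sorted(
        t for t in cands if category_of(schema, t).value == "Problem"
    )
    for i in range(config.n_stoplist_traps):
        if not trap_keys:
            raise GenerationError("lexicon contains no stoplisted term to build traps from")
        if not problem_types:
            raise GenerationError("no Problem-type terms available for traps")
        t1 = problem_types[rng.randrange(len(problem_types))]
        cid, surface = rng.choice(cands[t1])
        trap = trap_keys[rng.randrange(len(trap_keys))]
        items = (
            [("slot", 1)]
            + [("tok", w) for w in trap_words]
            + [("tok", trap)]
            + [("tok", w) for w in trap_tail]
        )
        fillers = {1: (cid, surface, t1, category_of(schema, t1).value)}
        doc, mentions = _assemble(f"trap{i:04d}", items, fillers)
        documents.append(doc)
        gold_mentions.append(mentions[1])

    return SyntheticCorpus(
        documents=documents, gold_mentions=gold_mentions, gold_triples=gold_triples
    )


# --- perturbation -----------------------------------------------------------

_MAX_RETRIES = 8


def _shift_boundary(
    m: EntityMention, doc: Document, taken: set[tuple[int, int]], golds: set
) -> EntityMention:
    """Extend or truncate a mention span by one token (boundary error)."""
    candidates: list[tuple[int, int]] = []
    if " " in m.surface:  # drop the last token
        new_end = m.start + len(m.surface.rsplit(" ", 1)[0])
        candidates.append((m.start, new_end))
    j = m.end
    while j < len(doc.text) and doc.text[j].isspace():
        j += 1
    k = j
    while k < len(doc.text) and not doc.text[k].isspace():
        k += 1
    if k > j:  # absorb the following token
        candidates.append((m.start, k))
    for start, end in candidates:
        if (m.doc_id, start, end, m.semantic_type) in golds or (start, end) in taken:
            continue
        return dataclasses.replace(
            m, start=start, end=end, surface=doc.text[start:end]
        )
    raise GenerationError(f"cannot perturb boundary of mention at {m.start}-{m.end}")


def perturb(
    documents: Sequence[Document],
    mentions: Sequence[EntityMention],
    schema: SemanticSchema,
    config: PerturbConfig,
) -> list[EntityMention]:
    """Inject exactly ⌊rate·N⌋ boundary and type errors into gold mentions.

    The sample is seeded and deterministic; untouched mentions are
    returned verbatim, so evaluating the output against the input gold
    recovers the configured C/B/T counts exactly.
    """
    docs = {d.doc_id: d for d in documents}
    n = len(mentions)
    n_b = int(config.boundary_error_rate * n + 1e-9)
    n_t = int(config.type_error_rate * n + 1e-9)
    if n_b + n_t > n:
        raise ValueError("requested more errors than mentions")
    rng = random.Random(config.rng_seed)
    chosen = rng.sample(range(n), n_b + n_t)
    b_idx, t_idx = set(chosen[:n_b]), set(chosen[n_b:])
    golds = {(m.doc_id, m.start, m.end, m.semantic_type) for m in mentions}
    other_types = {
        orig: [t for t in sorted(schema.types) if t != orig and schema.types[t].category.value != "Other"]
        for orig in {m.semantic_type for m in mentions}
    }
    out: list[EntityMention] = []
    taken: dict[str, set[tuple[int, int]]] = {}
    for i, m in enumerate(mentions):
        doc_taken = taken.setdefault(m.doc_id, set())
        if i in b_idx:
            for attempt in range(_MAX_RETRIES):
                try:
                    new = _shift_boundary(m, docs[m.doc_id], doc_taken, golds)
                    break
                except GenerationError:
                    if attempt == _MAX_RETRIES - 1:
                        raise
        elif i in t_idx:
            pool = other_types[m.semantic_type]
            if not pool:
                raise GenerationError("no alternative semantic type available")
            new = dataclasses.replace(m, semantic_type=rng.choice(pool))
        else:
            new = m
        doc_taken.add((new.start, new.end))
        out.append(new)
    return out
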