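"""Boundary-weighted evaluation of entity recognition and relation P/R/F.

Entity predictions are judged against gold mentions as

* ``correct`` — identical span and identical semantic type,
* ``boundary_only`` — a gold mention of the same semantic type overlaps
  the prediction, but no exact-span same-type match exists,
* ``type_error`` — everything else, including predictions with no
  overlapping gold at all (so the three verdicts partition the
  predictions: C + B + T = N).

Boundary-only errors cost half a point:

    P = 100 * (C + 0.5 * B) / (C + B + T)

equivalently ``100 - Tr - Br/2`` with the type-error rate ``Tr = 100*T/N``
and boundary-error rate ``Br = 100*B/N``.

Relation extraction is scored with precision/recall/F over complete
triples: a predicted triple counts as correct only when the relation
matches and *both* argument mentions are exactly right (span and
semantic type) — correct argument extraction is mandatory.  Entity
recognition recall is deliberately not computed (it would require
exhaustive gold annotation of every entity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .ner import EntityMention
from .relations import RelationTriple

__all__ = [
    "CORRECT",
    "BOUNDARY_ONLY",
    "TYPE_ERROR",
    "EvalReport",
    "MentionEvalReport",
    "RelationEvalReport",
    "TypeCounts",
    "evaluate_mentions",
    "f_measure",
    "judge_mention",
    "relation_prf",
    "round_half_up",
    "weighted_precision",
]

CORRECT = "correct"
BOUNDARY_ONLY = "boundary_only"
TYPE_ERROR = "type_error"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding (half away from zero); internal math stays unrounded."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _overlaps(a: EntityMention, b: EntityMention) -> bool:
    return a.start < b.end and b.start < a.end


def _same_head(pred: EntityMention, gold: EntityMention) -> bool:
    # head token = last whitespace-delimited token; compare its span
    return (
        pred.end == gold.end
        and pred.surface.split()[-1:] == gold.surface.split()[-1:]
    )


def judge_mention(
    pred: EntityMention,
    gold_mentions: Sequence[EntityMention],
    boundary_criterion: str = "overlap",
) -> str:
    """Judge one predicted mention; see module docstring for the verdicts.

    ``boundary_criterion`` is "overlap" (≥1 shared character with a
    same-type gold mention) or "head" (shared head token).
    """
    golds = [g for g in gold_mentions if g.doc_id == pred.doc_id]
    for g in golds:
        if (g.start, g.end) == (pred.start, pred.end) and g.semantic_type == pred.semantic_type:
            return CORRECT
    near = _overlaps if boundary_criterion == "overlap" else _same_head
    for g in golds:
        if g.semantic_type == pred.semantic_type and near(pred, g):
            return BOUNDARY_ONLY
    return TYPE_ERROR


def weighted_precision(C: int, B: int, T: int) -> float:
    """Boundary-weighted precision in percent; undefined (error) for N = 0."""
    n = C + B + T
    if n == 0:
        raise ValueError("weighted precision is undefined for N = 0")
    return 100.0 * (C + 0.5 * B) / n


@dataclass
class TypeCounts:
    C: int = 0
    B: int = 0
    T: int = 0

    @property
    def N(self) -> int:
        return self.C + self.B + self.T

    @property
    def type_error_rate(self) -> float:
        return 100.0 * self.T / self.N

    @property
    def boundary_error_rate(self) -> float:
        return 100.0 * self.B / self.N

    @property
    def precision(self) -> float:
        return weighted_precision(self.C, self.B, self.T)


@dataclass
class MentionEvalReport:
    C: int
    B: int
    T: int
    per_type: dict[str, TypeCounts]

    @property
    def N(self) -> int:
        return self.C + self.B + self.T

    @property
    def weighted_precision(self) -> float:
        return weighted_precision(self.C, self.B, self.T)


def evaluate_mentions(
    predictions: Sequence[EntityMention],
    gold_mentions: Sequence[EntityMention],
    boundary_criterion: str = "overlap",
) -> MentionEvalReport:
    """Count C/B/T overall and per predicted semantic type."""
    per_type: dict[str, TypeCounts] = {}
    totals = TypeCounts()
    for pred in predictions:
        verdict = judge_mention(pred, gold_mentions, boundary_criterion)
        tc = per_type.setdefault(pred.semantic_type, TypeCounts())
        for bucket in (tc, totals):
            if verdict == CORRECT:
                bucket.C += 1
            elif verdict == BOUNDARY_ONLY:
                bucket.B += 1
            else:
                bucket.T += 1
    return MentionEvalReport(C=totals.C, B=totals.B, T=totals.T, per_type=per_type)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (both in percent)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class RelationEvalReport:
    precision: float
    recall: float
    f: float
    precision_defined: bool
    recall_defined: bool
    n_pred: int
    n_gold: int
    n_correct: int


def _triple_key(t: RelationTriple) -> tuple:
    return (
        t.source.doc_id,
        t.relation,
        t.source.start,
        t.source.end,
        t.source.semantic_type,
        t.target.start,
        t.target.end,
        t.target.semantic_type,
    )


def relation_prf(
    pred_triples: Iterable[RelationTriple],
    gold_triples: Iterable[RelationTriple],
) -> RelationEvalReport:
    """Precision/recall/F over complete triples (exact-argument matching).

    An empty prediction set leaves precision undefined (reported as 0
    with ``precision_defined=False``); an empty gold set likewise for
    recall.
    """
    pred = {_triple_key(t) for t in pred_triples}
    gold = {_triple_key(t) for t in gold_triples}
    correct = len(pred & gold)
    p_def, r_def = bool(pred), bool(gold)
    p = 100.0 * correct / len(pred) if p_def else 0.0
    r = 100.0 * correct / len(gold) if r_def else 0.0
    f = f_measure(p, r) if (p_def and r_def) else 0.0
    return RelationEvalReport(
        precision=p,
        recall=r,
        f=f,
        precision_defined=p_def,
        recall_defined=r_def,
        n_pred=len(pred),
        n_gold=len(gold),
        n_correct=correct,
    )


@dataclass
class EvalReport:
    """Combined entity + relation report, serializable for the CLI."""

    entity: MentionEvalReport
    relation: RelationEvalReport

    def to_dict(self) -> dict:
        per_type = {
            name: {
                "C": tc.C,
                "B": tc.B,
                "T": tc.T,
                "N": tc.N,
                "Tr": round_half_up(tc.type_error_rate),
                "Br": round_half_up(tc.boundary_error_rate),
                "P": round_half_up(tc.precision),
            }
            for name, tc in sorted(self.entity.per_type.items())
        }
        return {
            "entity": {
                "C": self.entity.C,
                "B": self.entity.B,
                "T": self.entity.T,
                "N": self.entity.N,
                "weighted_precision": round_half_up(self.entity.weighted_precision)
                if self.entity.N
                else None,
                "per_type": per_type,
            },
            "relation": {
                "precision": round_half_up(self.relation.precision),
                "recall": round_half_up(self.relation.recall),
                "f_measure": round_half_up(self.relation.f),
                "precision_defined": self.relation.precision_defined,
                "recall_defined": self.relation.recall_defined,
                "n_pred": self.relation.n_pred,
                "n_gold": self.relation.n_gold,
                "n_correct": self.relation.n_correct,
            },
        }
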