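"""Entity-level exact-match scoring and token-level confusion matrices.

A predicted mention is a true positive iff its (start, end, entity type)
triple matches a gold mention of the same document exactly, matched
one-to-one.  Nested gold mentions are scored independently, so a system can
earn credit for both the outer and the inner span.  Precision, recall and
F1 are reported as percentages; a zero denominator yields 0.0 with the
``undefined`` flag set on the report row.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codec import OUTSIDE, TagSchema
from .standoff import AnnotatedDocument, EntityMention

__all__ = ["TypeScore", "PRFReport", "entity_prf", "confusion_matrix"]


@dataclass
class TypeScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    undefined_precision: bool = False
    undefined_recall: bool = False

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class PRFReport:
    per_type: dict[str, TypeScore]
    micro: TypeScore

    def to_frame(self) -> pd.DataFrame:
        rows = {
            t: {"precision": s.precision, "recall": s.recall, "f1": s.f1,
                "tp": s.tp, "fp": s.fp, "fn": s.fn}
            for t, s in sorted(self.per_type.items())
        }
        rows["micro-average"] = {
            "precision": self.micro.precision, "recall": self.micro.recall,
            "f1": self.micro.f1, "tp": self.micro.tp, "fp": self.micro.fp,
            "fn": self.micro.fn,
        }
        return pd.DataFrame(rows).T

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", float_format="%.2f")

    def __str__(self) -> str:
        return self.to_frame().to_string(float_format=lambda x: f"{x:.2f}")


def _mention_keys(mentions: Iterable[EntityMention]) -> list[tuple[int, int, str]]:
    return [(m.start, m.end, m.entity_type) for m in mentions]


def entity_prf(
    gold: Mapping[str, Iterable[EntityMention]] | Sequence[AnnotatedDocument],
    pred: Mapping[str, Iterable[EntityMention]] | Sequence[AnnotatedDocument],
    deduplicate: bool = True,
) -> PRFReport:
    """Exact-boundary, exact-type entity P/R/F1, per type and micro-averaged.

    ``gold`` and ``pred`` are either mappings doc_id → mentions or
    sequences of :class:`AnnotatedDocument`; the two sides must cover the
    same doc_ids.  With ``deduplicate`` (default), identical predicted
    (start, end, type) triples count once.
    """
    gold = _as_mapping(gold)
    pred = _as_mapping(pred)
    if set(gold) != set(pred):
        missing = set(gold) ^ set(pred)
        raise ValueError(f"gold/pred doc_id mismatch: {sorted(missing)}")

    scores: dict[str, TypeScore] = {}

    def score_for(etype: str) -> TypeScore:
        return scores.setdefault(etype, TypeScore())

    for doc_id in gold:
        gold_keys = Counter(_mention_keys(gold[doc_id]))
        pred_keys = _mention_keys(pred[doc_id])
        if deduplicate:
            pred_counter = Counter(dict.fromkeys(pred_keys, 1))
        else:
            pred_counter = Counter(pred_keys)
        for key, n_pred in pred_counter.items():
            n_gold = gold_keys.get(key, 0)
            matched = min(n_pred, n_gold)
            s = score_for(key[2])
            s.tp += matched
            s.fp += n_pred - matched
        for key, n_gold in gold_keys.items():
            n_pred = pred_counter.get(key, 0)
            score_for(key[2]).fn += max(0, n_gold - min(n_pred, n_gold))

    micro = TypeScore(
        tp=sum(s.tp for s in scores.values()),
        fp=sum(s.fp for s in scores.values()),
        fn=sum(s.fn for s in scores.values()),
    )
    for s in list(scores.values()) + [micro]:
        s.undefined_precision = (s.tp + s.fp) == 0
        s.undefined_recall = (s.tp + s.fn) == 0
    return PRFReport(scores, micro)


def _as_mapping(side) -> dict[str, list[EntityMention]]:
    if isinstance(side, Mapping):
        return {k: list(v) for k, v in side.items()}
    return {doc.doc_id: list(doc.mentions) for doc in side}


def confusion_matrix(
    gold_tags: Sequence[str], pred_tags: Sequence[str], schema: TagSchema
) -> pd.DataFrame:
    """Token-level confusion matrix over entity types (prefixes collapsed,
    V collapsing to the V tag's type) plus the O class.  Rows are gold,
    columns predictions; row sums equal gold per-type token counts."""
    if len(gold_tags) != len(pred_tags):
        raise ValueError(
            f"length mismatch: {len(gold_tags)} gold vs {len(pred_tags)} predicted"
        )
    labels = list(schema.entity_types) + [OUTSIDE]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)

    def collapse(tag: str) -> str:
        _prefix, etype = schema.split(tag)
        return etype if etype is not None else OUTSIDE

    for g, p in zip(gold_tags, pred_tags):
        mat.loc[collapse(g), collapse(p)] += 1
    return mat
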