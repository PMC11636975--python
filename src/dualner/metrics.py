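"""Entity-level evaluation for BIO tag sequences.

Entities are maximal ``B-X (I-X)*`` runs. Prediction quality is scored with
STRICT matching: a predicted span is a true positive only when its start, end
and type all coincide with a gold span. Precision, recall and F1 are
micro-averaged over the corpus and reported as percentages; accuracy is the
token-level fraction of exactly matching tags (including O).

Ill-formed sequences are repaired the way the classic conlleval scorer does:
an ``I-X`` that does not continue a ``B-X``/``I-X`` run opens a new X entity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import OUTSIDE


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open character span ``[start, end)`` of one typed entity."""

    start: int
    end: int
    type: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def extract_entities(tags: Sequence[str]) -> set[EntitySpan]:
    """Extract typed spans from a BIO tag sequence (with repair)."""
    spans: set[EntitySpan] = set()
    start = -1
    cur_type = None
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if cur_type is not None:
                spans.add(EntitySpan(start, i, cur_type))
            cur_type, start = tag[2:], i
        elif tag.startswith("I-"):
            t = tag[2:]
            if cur_type != t:
                # repair: orphan I-X (after O or a different type) opens a span
                if cur_type is not None:
                    spans.add(EntitySpan(start, i, cur_type))
                cur_type, start = t, i
        else:  # O (anything that is not B-/I- closes the run)
            if cur_type is not None:
                spans.add(EntitySpan(start, i, cur_type))
                cur_type = None
    if cur_type is not None:
        spans.add(EntitySpan(start, len(tags), cur_type))
    return spans


@dataclass
class MetricReport:
    """Micro-averaged entity scores plus token accuracy, as percentages.

    ``tp``/``fp``/``fn`` are entity-span counts; ``tn`` counts tokens where
    gold and prediction are both O (entities have no natural true negative).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_tokens: int
    n_correct_tokens: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct_tokens / self.n_tokens if self.n_tokens else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        """conlleval-style one-block text summary."""
        return (
            f"processed {self.n_tokens} tokens; "
            f"found: {self.tp + self.fp} entities; correct: {self.tp}.\n"
            f"accuracy: {self.accuracy:6.2f}%; precision: {self.precision:6.2f}%; "
            f"recall: {self.recall:6.2f}%; FB1: {self.f1:6.2f}"
        )


class AlignmentError(ValueError):
    """Gold and predicted tag sequences disagree in shape."""


def score(
    gold: Iterable[Sequence[str]],
    pred: Iterable[Sequence[str]],
    per_type: bool = False,
) -> MetricReport | tuple[MetricReport, dict[str, MetricReport]]:
    """Score predicted BIO sequences against gold, micro-averaged.

    ``gold`` and ``pred`` are parallel iterables of per-sentence tag lists.
    With ``per_type=True`` additionally returns a per-entity-type breakdown
    (token tallies in the breakdown refer to the whole corpus).
    """
    gold = list(gold)
    pred = list(pred)
    if len(gold) != len(pred):
        raise AlignmentError(f"{len(gold)} gold vs {len(pred)} predicted sentences")
    tp = fp = fn = tn = n_tok = n_ok = 0
    by_type: dict[str, list[int]] = {}
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise AlignmentError(f"sentence {i}: {len(g)} gold vs {len(p)} pred tags")
        n_tok += len(g)
        n_ok += sum(1 for a, b in zip(g, p) if a == b)
        tn += sum(1 for a, b in zip(g, p) if a == OUTSIDE and b == OUTSIDE)
        gs, ps = extract_entities(g), extract_entities(p)
        tp += len(gs & ps)
        fp += len(ps - gs)
        fn += len(gs - ps)
        if per_type:
            for t in {s.type for s in gs | ps}:
                gt = {s for s in gs if s.type == t}
                pt = {s for s in ps if s.type == t}
                acc = by_type.setdefault(t, [0, 0, 0])
                acc[0] += len(gt & pt)
                acc[1] += len(pt - gt)
                acc[2] += len(gt - pt)
    report = MetricReport(tp, fp, fn, tn, n_tok, n_ok)
    if not per_type:
        return report
    breakdown = {
        t: MetricReport(a[0], a[1], a[2], tn, n_tok, n_ok)
        for t, a in sorted(by_type.items())
    }
    return report, breakdown
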