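"""Entity-level evaluation: precision, recall, F1 under exact matching.

A predicted mention counts as a true positive iff its (start, end, label)
triple appears in the gold set of the same sentence.  Micro scores pool
TP/FP/FN over all sentences and types; per-type scores restrict to one label.
Zero denominators yield 0 by convention.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import EntityMention, Sentence


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_type: dict[str, "MatchCounts"] = field(default_factory=dict)

    def add(self, other: "MatchCounts") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        for label, counts in other.per_type.items():
            mine = self.per_type.setdefault(label, MatchCounts())
            mine.tp += counts.tp
            mine.fp += counts.fp
            mine.fn += counts.fn


def match_mentions(pred: Iterable[EntityMention],
                   gold: Iterable[EntityMention]) -> MatchCounts:
    """Exact (start, end, label) set matching for one sentence."""
    pred_keys = {m.key for m in pred}
    gold_keys = {m.key for m in gold}
    counts = MatchCounts(tp=len(pred_keys & gold_keys),
                         fp=len(pred_keys - gold_keys),
                         fn=len(gold_keys - pred_keys))
    by_label: dict[str, tuple[set, set]] = defaultdict(lambda: (set(), set()))
    for key in pred_keys:
        by_label[key[2]][0].add(key)
    for key in gold_keys:
        by_label[key[2]][1].add(key)
    for label, (p, g) in by_label.items():
        counts.per_type[label] = MatchCounts(tp=len(p & g), fp=len(p - g),
                                             fn=len(g - p))
    return counts


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) from pooled counts; 0 on empty denominators."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def evaluate_corpus(predictions: Sequence[Sequence[EntityMention]],
                    gold: Sequence[Sentence]) -> dict:
    """Micro and per-type P/R/F1 over a corpus of per-sentence predictions."""
    if len(predictions) != len(gold):
        raise ValueError("prediction and gold corpora differ in length")
    total = MatchCounts()
    for pred, sent in zip(predictions, gold):
        total.add(match_mentions(pred, sent.mentions))
    p, r, f1 = prf(total)
    report = {
        "overall": {"P": p, "R": r, "F1": f1,
                    "TP": total.tp, "FP": total.fp, "FN": total.fn},
        "per_type": {},
    }
    for label in sorted(total.per_type):
        tp_, rp_, f1_ = prf(total.per_type[label])
        c = total.per_type[label]
        report["per_type"][label] = {"P": tp_, "R": rp_, "F1": f1_,
                                     "TP": c.tp, "FP": c.fp, "FN": c.fn}
    return report
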