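"""Decoding: from span scores and boundary probabilities to a nested entity set.

Three stages:

1. ``predict_span_labels`` — per enumerated span, take the argmax class over
   the score tensor; spans whose best class is non-entity are dropped.
2. ``boundary_gate`` — optionally keep only candidates whose start and end
   tokens the boundary detector marks as inside (P(I) >= threshold, or the
   gold I label when gold boundaries are supplied).
3. ``resolve_overlaps`` — greedy sweep in descending score order; a candidate
   is kept iff it does not *cross* any already-kept mention.  Two spans cross
   when they partially overlap without containment (a.start < b.start <=
   a.end < b.end, in either order); containment and disjointness never block,
   so properly nested predictions survive.

Ties in the descending sort break by (start, end, label) for determinism.
"""

from __future__ import annotations

import numpy as np

from .boundary import I_INDEX
from .config import ModelConfig
from .corpus import EntityMention, LabelSet


def predict_span_labels(scores: np.ndarray, label_set: LabelSet,
                        max_span: int | None = None,
                        rank_by: str = "score") -> list[EntityMention]:
    """Argmax class per enumerated span; non-entity argmaxes are discarded.

    `scores` has shape (N, N, C') with class index 0 = non-entity.  The
    returned mentions carry the winning class's raw score (or its softmax
    probability with ``rank_by="probability"``) for downstream ranking.
    """
    n = scores.shape[0]
    best = scores.argmax(axis=-1)
    if rank_by == "probability":
        shifted = scores - scores.max(axis=-1, keepdims=True)
        expd = np.exp(shifted)
        value = expd / expd.sum(axis=-1, keepdims=True)
    else:
        value = scores
    candidates = []
    for i in range(n):
        j_hi = n if max_span is None else min(n, i + max_span)
        for j in range(i, j_hi):
            c = best[i, j]
            if c == 0:
                continue
            candidates.append(EntityMention(i, j, label_set.label(c),
                                            score=float(value[i, j, c])))
    return candidates


def boundary_gate(candidates: list[EntityMention],
                  boundary: np.ndarray,
                  threshold: float = 0.5) -> list[EntityMention]:
    """Keep candidates whose start and end tokens the boundary task marks I.

    `boundary` is either a (T, 2) probability array (test time: the gate
    predicate is P(I) >= threshold at both endpoints) or a (T,) integer
    array of gold 0/1 labels (both endpoints must be 1).  A threshold of 0
    passes everything.
    """
    boundary = np.asarray(boundary)
    if boundary.ndim == 2:
        inside = boundary[:, I_INDEX] >= threshold
    else:
        inside = boundary.astype(bool)
    if threshold == 0 and boundary.ndim == 2:
        return list(candidates)
    return [m for m in candidates if inside[m.start] and inside[m.end]]


def resolve_overlaps(candidates: list[EntityMention]) -> list[EntityMention]:
    """Greedy highest-score-first selection of a crossing-free mention set.

    Candidates are visited in descending score order (ties by start, end,
    label); each is kept iff it crosses no already-kept mention.  The result
    is sorted by (start, end, label).
    """
    ranked = sorted(candidates,
                    key=lambda m: (-(m.score if m.score is not None else 0.0),
                                   m.start, m.end, m.label))
    kept: list[EntityMention] = []
    for cand in ranked:
        if not any(cand.crosses(k) for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda m: m.key)


def decode_sentence(scores: np.ndarray,
                    boundary: np.ndarray | None,
                    label_set: LabelSet,
                    cfg: ModelConfig) -> list[EntityMention]:
    """Full decode: span argmax -> boundary gate (if enabled) -> overlap
    resolution.  Deterministic given the model outputs."""
    n = scores.shape[0]
    candidates = predict_span_labels(scores, label_set,
                                     max_span=cfg.effective_max_span(n),
                                     rank_by=cfg.rank_by)
    if cfg.gating_enabled and boundary is not None:
        candidates = boundary_gate(candidates, boundary, cfg.gate_threshold)
    return resolve_overlaps(candidates)
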