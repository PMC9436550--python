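"""Biaffine span classification.

Every candidate span (i, j) with i <= j receives one score per class from
the biaffine form

    r_m(i, j) = s(i)^T U1 e(j) + U2 [s(i) (+) e(j)] + b

where s(i), e(j) are the head/tail representations of the span's start and
end tokens, U1 is a (d x C' x d) bilinear tensor, U2 a linear map on the
concatenation, b a per-class bias, and C' the number of entity types plus
the non-entity class.  By default s and e are augmented with a constant-1
coordinate inside the bilinear term (standard biaffine practice); disable
with ``biaffine_bias: false`` for the strictly bilinear form.

The training objective assigns every enumerated span its gold class (the
matching gold mention's type, else non-entity) and applies softmax
cross-entropy, averaged over enumerated spans (``loss_reduction: sum``
restores the summed objective).
"""

from __future__ import annotations

import logging

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

logger = logging.getLogger(__name__)


class BiaffineScorer(nn.Module):
    def __init__(self, d: int, n_classes: int, rng: np.random.Generator,
                 bias_augmented: bool = True):
        self.d = d
        self.n_classes = n_classes
        self.bias_augmented = bias_augmented
        d1 = d + 1 if bias_augmented else d
        # zero-init scoring maps: early scores are driven by the class bias
        # alone, so the bilinear term never injects noise that the linear
        # terms must first unlearn
        self.U1 = Tensor(np.zeros((d1, n_classes, d1)), requires_grad=True)
        self.U2 = Tensor(np.zeros((2 * d, n_classes)), requires_grad=True)
        self.b = Tensor(np.zeros(n_classes), requires_grad=True)
        self._rng = rng  # kept for randomised re-init in experiments/tests

    def randomise(self, scale: float = 0.1) -> None:
        """Re-draw the scoring maps uniformly in [-scale, scale]."""
        self.U1.data = self._rng.uniform(-scale, scale, size=self.U1.shape)
        self.U2.data = self._rng.uniform(-scale, scale, size=self.U2.shape)

    def __call__(self, s: Tensor, e: Tensor) -> Tensor:
        """Score tensor r_m of shape (B, N, N, C'); entry (b, i, j, c) scores
        span (i, j) of sentence b for class c.  Entries with j < i are
        computed but masked out downstream."""
        B, N, d = s.shape
        C = self.n_classes
        if self.bias_augmented:
            ones = Tensor(np.ones((B, N, 1)))
            s1 = ad.concat([s, ones], axis=-1)
            e1 = ad.concat([e, ones], axis=-1)
        else:
            s1, e1 = s, e
        d1 = s1.shape[-1]
        # bilinear term: s1[b,i] . U1[:,c,:] . e1[b,j]
        a = ad.reshape(ad.reshape(s1, (B * N, d1)) @ ad.reshape(self.U1, (d1, C * d1)),
                       (B, N, C, d1))
        a = ad.transpose(a, (0, 2, 1, 3))                       # (B, C, N, d1)
        e_t = ad.reshape(ad.transpose(e1, (0, 2, 1)), (B, 1, d1, N))
        bilinear = ad.transpose(a @ e_t, (0, 2, 3, 1))          # (B, N, N, C)
        # linear term on the concatenation, split into start and end halves
        lin_s = ad.reshape(s @ self.U2[:d, :], (B, N, 1, C))
        lin_e = ad.reshape(e @ self.U2[d:, :], (B, 1, N, C))
        return bilinear + lin_s + lin_e + self.b


def score_spans(s: Tensor, e: Tensor, scorer: BiaffineScorer) -> Tensor:
    """Functional alias for :meth:`BiaffineScorer.__call__`."""
    return scorer(s, e)


def span_class_probs(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Per-span class distribution: softmax of the score tensor over classes."""
    shifted = scores - scores.max(axis=axis, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=axis, keepdims=True)


def span_gold_assignment(sentence, label_set, max_span: int | None = None,
                         size: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gold class index for every (i, j) cell plus the enumeration mask.

    Cells are 0 (non-entity) unless a gold mention occupies (i, j).  The mask
    selects i <= j < len with span length <= `max_span`; gold mentions longer
    than the cap fall outside the enumeration and are logged.
    """
    n = len(sentence)
    size = size or n
    gold = np.zeros((size, size), dtype=np.int64)
    idx = np.arange(size)
    mask = (idx[:, None] <= idx[None, :]) & (idx[None, :] < n)
    if max_span is not None:
        mask &= (idx[None, :] - idx[:, None]) < max_span
    for m in sentence.mentions:
        if max_span is not None and (m.end - m.start) >= max_span:
            logger.warning("gold mention %s longer than span cap %d; excluded "
                           "from the classification loss", m.key, max_span)
            continue
        gold[m.start, m.end] = label_set.index(m.label)
    return gold, mask


def span_classification_loss(scores: Tensor, gold: np.ndarray, mask: np.ndarray,
                             reduction: str = "mean") -> Tensor:
    """Softmax cross-entropy over enumerated spans (loss_b).

    `scores`: (B, N, N, C') span scores; `gold`: (B, N, N) gold class
    indices; `mask`: (B, N, N) enumeration mask.  Reduction is the mean over
    enumerated spans by default.
    """
    logp = ad.log_softmax(scores, axis=-1)
    picked = ad.gather(logp, gold[..., None], axis=-1)
    nll = -1.0 * ad.reshape(picked, gold.shape) * Tensor(mask.astype(float))
    total = nll.sum()
    if reduction == "mean":
        return total * (1.0 / max(int(mask.sum()), 1))
    return total
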