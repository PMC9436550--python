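"""Boundary detection: the auxiliary per-token O/I task.

The head consumes the same head/tail representations the span classifier
uses — this sharing is what lets the auxiliary supervision sharpen the span
representations.  For each token t the concatenation [s(t), e(t)] passes
through ReLU and a linear map to two logits O_t, and d(t) = softmax(O_t)
gives the probability that the token is outside (O) or inside (I) an entity.
``boundary_activation: none`` drops the ReLU for a purely affine head.

Class order is fixed as (O, I): index 0 = O, index 1 = I.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

O_INDEX, I_INDEX = 0, 1


class BoundaryHead(nn.Module):
    def __init__(self, d: int, rng: np.random.Generator, activation: str = "relu"):
        if activation not in ("relu", "none"):
            raise ValueError("activation must be relu or none")
        self.activation = activation
        self.linear = nn.Linear(2 * d, 2, rng)

    def __call__(self, s: Tensor, e: Tensor) -> Tensor:
        """Per-token boundary logits O_t, shape (B, T, 2)."""
        x = ad.concat([s, e], axis=-1)
        if self.activation == "relu":
            x = ad.relu(x)
        return self.linear(x)


def boundary_logits(s: Tensor, e: Tensor, head: BoundaryHead) -> Tensor:
    """Functional alias for :meth:`BoundaryHead.__call__`."""
    return head(s, e)


def boundary_probs(logits: np.ndarray) -> np.ndarray:
    """d(t) = softmax(O_t): per-token (P(O), P(I)), rows summing to 1."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=-1, keepdims=True)


def boundary_loss(logits: Tensor, gold: np.ndarray, token_mask: np.ndarray,
                  reduction: str = "mean") -> Tensor:
    """Cross-entropy between predicted d(t) and gold one-hot labels (loss_d),
    averaged over real (unpadded) tokens.

    `logits`: (B, T, 2); `gold`: (B, T) in {0, 1}; `token_mask`: (B, T).
    """
    if logits.shape[:2] != gold.shape:
        raise ValueError(f"length mismatch: logits {logits.shape} vs gold {gold.shape}")
    logp = ad.log_softmax(logits, axis=-1)
    picked = ad.gather(logp, gold[..., None], axis=-1)
    nll = -1.0 * ad.reshape(picked, gold.shape) * Tensor(token_mask.astype(float))
    total = nll.sum()
    if reduction == "mean":
        return total * (1.0 / max(int(token_mask.sum()), 1))
    return total
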