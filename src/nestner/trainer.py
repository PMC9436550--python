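"""Joint training of span classification and boundary detection.

The two heads are optimised together under the multi-task objective

    Multi_Loss = loss_b + alpha * loss_d

with Adam.  The boundary regime is teacher-forced: during training the
boundary head is supervised with gold O/I labels (and decoding, if gating is
on, would use gold boundaries), while evaluation passes gate candidate spans
with the *predicted* boundary probabilities.  The span-classification loss
always covers every enumerated span, so gating affects decoding only.

Early stopping monitors held-out micro-F1 with a configurable patience; the
best parameter snapshot is restored at the end of training.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .biaffine import span_classification_loss, span_gold_assignment
from .boundary import boundary_loss, boundary_probs
from .config import ModelConfig
from .corpus import EntityMention, Sentence, Vocabulary, make_boundary_labels
from .decoder import decode_sentence
from .metrics import evaluate_corpus
from .model import NestedNERModel
from .nn import Adam

logger = logging.getLogger(__name__)


def multi_task_loss(loss_b: Tensor | float, loss_d: Tensor | float,
                    alpha: float) -> Tensor | float:
    """Multi_Loss = loss_b + alpha * loss_d, with alpha >= 0."""
    if alpha < 0:
        raise ValueError("alpha (mixing ratio) must be >= 0")
    return loss_b + alpha * loss_d


@dataclass
class TrainState:
    epoch: int = 0
    best_f1: float = -1.0
    best_epoch: int = -1
    best_params: dict | None = None
    log: list[dict] = field(default_factory=list)


# ------------------------------------------------------------------ batching
def collate(sentences: list[Sentence], vocab: Vocabulary, cfg: ModelConfig) -> dict:
    """Pad a list of sentences into dense index arrays plus gold targets."""
    B = len(sentences)
    T = max(len(s) for s in sentences)
    min_chars = max(cfg.char_filter_widths)
    Lc = max(min_chars, max(len(tok) for s in sentences for tok in s.tokens))
    word_ids = np.zeros((B, T), dtype=np.int64)
    char_ids = np.zeros((B, T, Lc), dtype=np.int64)
    word_lens = np.zeros((B, T), dtype=np.int64)
    token_mask = np.zeros((B, T), dtype=bool)
    span_gold = np.zeros((B, T, T), dtype=np.int64)
    span_mask = np.zeros((B, T, T), dtype=bool)
    boundary_gold = np.zeros((B, T), dtype=np.int64)
    for b, sent in enumerate(sentences):
        n = len(sent)
        token_mask[b, :n] = True
        for t, tok in enumerate(sent.tokens):
            word_ids[b, t] = vocab.word_id(tok)
            word_lens[b, t] = min(len(tok), Lc)
            for k, ch in enumerate(tok[:Lc]):
                char_ids[b, t, k] = vocab.char_id(ch)
        gold, mask = span_gold_assignment(sent, vocab.labels,
                                          max_span=cfg.effective_max_span(n),
                                          size=T)
        span_gold[b], span_mask[b] = gold, mask
        boundary_gold[b, :n] = make_boundary_labels(sent, cfg.boundary_scheme)
    return {
        "tokens": [s.tokens for s in sentences],
        "word_ids": word_ids, "char_ids": char_ids, "word_lens": word_lens,
        "token_mask": token_mask, "span_gold": span_gold,
        "span_mask": span_mask, "boundary_gold": boundary_gold,
        "lengths": np.array([len(s) for s in sentences]),
    }


def batch_losses(model: NestedNERModel, batch: dict,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, Tensor]:
    """(loss_b, loss_d) for one collated batch."""
    span_scores, bnd_logits = model(batch, rng)
    loss_b = span_classification_loss(span_scores, batch["span_gold"],
                                      batch["span_mask"],
                                      reduction=model.cfg.loss_reduction)
    loss_d = boundary_loss(bnd_logits, batch["boundary_gold"],
                           batch["token_mask"],
                           reduction=model.cfg.loss_reduction)
    return loss_b, loss_d


# ------------------------------------------------------------------ training
def train(model: NestedNERModel, train_sents: list[Sentence],
          dev_sents: list[Sentence] | None, cfg: ModelConfig) -> list[dict]:
    """Train in place; returns the per-epoch log (losses and dev P/R/F1)."""
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    order_rng = np.random.default_rng(rng.integers(2**31))
    optimiser = Adam(model.parameters(), lr=cfg.learning_rate)
    state = TrainState()
    # sort by length so batches are width-homogeneous, then shuffle batch order
    by_length = sorted(range(len(train_sents)), key=lambda i: len(train_sents[i]))
    batches_idx = [by_length[i:i + cfg.batch_size]
                   for i in range(0, len(by_length), cfg.batch_size)]
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order_rng.shuffle(batches_idx)
        sums = {"loss_b": 0.0, "loss_d": 0.0, "multi_loss": 0.0}
        for idx in batches_idx:
            batch = collate([train_sents[i] for i in idx], model.vocab, cfg)
            loss_b, loss_d = batch_losses(model, batch, drop_rng)
            total = multi_task_loss(loss_b, loss_d, cfg.alpha)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} on a batch of "
                    f"{len(idx)} sentences (loss_b={loss_b.item()}, "
                    f"loss_d={loss_d.item()})")
            model.zero_grad()
            total.backward()
            optimiser.step()
            sums["loss_b"] += loss_b.item() * len(idx)
            sums["loss_d"] += loss_d.item() * len(idx)
            sums["multi_loss"] += total.item() * len(idx)
        record = {"epoch": epoch,
                  **{k: v / len(train_sents) for k, v in sums.items()}}
        if dev_sents:
            predictions = predict(model, dev_sents, cfg)
            report = evaluate_corpus(predictions, dev_sents)
            record.update(dev_P=report["overall"]["P"],
                          dev_R=report["overall"]["R"],
                          dev_F1=report["overall"]["F1"])
            if record["dev_F1"] > state.best_f1:
                state.best_f1 = record["dev_F1"]
                state.best_epoch = epoch
                state.best_params = copy.deepcopy(model.state_dict())
        state.log.append(record)
        state.epoch = epoch
        logger.info("epoch %d: %s", epoch,
                    {k: round(v, 4) for k, v in record.items() if k != "epoch"})
        if dev_sents:
            if cfg.target_f1 is not None and state.best_f1 >= cfg.target_f1:
                break
            if epoch - state.best_epoch >= cfg.patience:
                break
    if state.best_params is not None:
        model.load_state_dict(state.best_params)
    return state.log


# ----------------------------------------------------------------- inference
def predict(model: NestedNERModel, sentences: list[Sentence],
            cfg: ModelConfig | None = None,
            batch_size: int | None = None) -> list[list[EntityMention]]:
    """Decode each sentence with predicted-boundary gating (evaluation mode)."""
    cfg = cfg or model.cfg
    batch_size = batch_size or cfg.batch_size
    model.eval()
    outputs: list[list[EntityMention]] = [None] * len(sentences)  # type: ignore
    order = sorted(range(len(sentences)), key=lambda i: len(sentences[i]))
    with ad.no_grad():
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            batch = collate([sentences[i] for i in idx], model.vocab, cfg)
            span_scores, bnd_logits = model(batch)
            probs = boundary_probs(bnd_logits.numpy())
            for row, i in enumerate(idx):
                n = len(sentences[i])
                outputs[i] = decode_sentence(
                    span_scores.numpy()[row, :n, :n, :],
                    probs[row, :n, :], model.vocab.labels, cfg)
    return outputs
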