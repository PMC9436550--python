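"""Sentence encoder: embeddings, BiLSTM, and head/tail span projections.

Each token t is embedded as the concatenation X_t = [X_t^lm ; X_t^char ;
X_t^word] — an optional frozen contextual block, a character-CNN block, and a
word-vector block (the contextual block is omitted entirely when no external
embedder is configured).  A stacked BiLSTM produces hidden states h_t, and
two independent MLPs specialise h_t into a head representation s(t) and a
tail representation e(t), which the span scorer and the boundary head share.

By default s(t), e(t) are the pre-softmax MLP outputs; ``span_repr:
post_softmax`` applies a per-token softmax over the representation instead
(the literal classifier-style reading).  The softmax views are also exposed
as auxiliary begin/end predictors via ``head_tail_project(...)``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .config import ModelConfig
from .corpus import Vocabulary

# Contract for an external contextual embedder: tokens -> (len(tokens), dim)
ContextualEmbedder = Callable[[Sequence[str]], np.ndarray]


class Encoder(nn.Module):
    def __init__(self, vocab: Vocabulary, cfg: ModelConfig,
                 rng: np.random.Generator,
                 word_vectors: np.ndarray | None = None,
                 contextual: ContextualEmbedder | None = None):
        self.cfg = cfg
        self.vocab = vocab
        self.contextual = contextual
        self.word_emb = nn.Embedding(vocab.n_words, cfg.word_dim, rng,
                                     init=word_vectors)
        self.char_cnn = nn.CharCNN(vocab.n_chars, cfg.char_dim,
                                   cfg.char_filter_widths, cfg.char_filters, rng)
        self.emb_dropout = nn.Dropout(cfg.emb_dropout)
        in_dim = cfg.word_dim + self.char_cnn.out_dim
        if contextual is not None:
            if cfg.contextual_dim is None:
                raise ValueError("contextual embedder given but contextual_dim unset")
            in_dim += cfg.contextual_dim
        self.bilstm = nn.BiLSTM(in_dim, cfg.lstm_size, cfg.lstm_layers,
                                cfg.lstm_dropout, rng)
        self.mlp_s = nn.Linear(cfg.lstm_size, cfg.mlp_size, rng)
        self.mlp_e = nn.Linear(cfg.lstm_size, cfg.mlp_size, rng)
        self.mlp_dropout = nn.Dropout(cfg.mlp_dropout)

    # ------------------------------------------------------------ embedding
    def embed_tokens(self, batch: dict, rng: np.random.Generator | None = None) -> Tensor:
        """Concatenated token embeddings X_t, shape (B, T, D)."""
        blocks: list[Tensor] = []
        if self.contextual is not None:
            blocks.append(Tensor(self._contextual_block(batch)))
        blocks.append(self.char_cnn(batch["char_ids"], batch["word_lens"]))
        blocks.append(self.word_emb(batch["word_ids"]))
        x = ad.concat(blocks, axis=-1)
        return self.emb_dropout(x, rng)

    def _contextual_block(self, batch: dict) -> np.ndarray:
        B, T = batch["word_ids"].shape
        out = np.zeros((B, T, self.cfg.contextual_dim))
        for b, tokens in enumerate(batch["tokens"]):
            vecs = np.asarray(self.contextual(tokens))
            if vecs.shape != (len(tokens), self.cfg.contextual_dim):
                raise ValueError(
                    f"contextual embedder returned shape {vecs.shape}, expected "
                    f"({len(tokens)}, {self.cfg.contextual_dim})")
            out[b, :len(tokens)] = vecs
        return out

    # -------------------------------------------------------------- encoder
    def bilstm_encode(self, x: Tensor, token_mask: np.ndarray,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Hidden states h_t = [forward ; backward], shape (B, T, lstm_size)."""
        return self.bilstm(x, token_mask, rng)

    def head_tail_project(self, h: Tensor, rng: np.random.Generator | None = None,
                          return_softmax: bool = False):
        """Head/tail representations s(t), e(t), each (B, T, mlp_size).

        With ``return_softmax`` the per-token softmax views (the auxiliary
        begin/end predictors) are returned as well.
        """
        s = self.mlp_dropout(ad.relu(self.mlp_s(h)), rng)
        e = self.mlp_dropout(ad.relu(self.mlp_e(h)), rng)
        soft_s, soft_e = ad.softmax(s, axis=-1), ad.softmax(e, axis=-1)
        if self.cfg.span_repr == "post_softmax":
            s, e = soft_s, soft_e
        if return_softmax:
            return s, e, soft_s, soft_e
        return s, e

    def __call__(self, batch: dict, rng: np.random.Generator | None = None):
        x = self.embed_tokens(batch, rng)
        h = self.bilstm_encode(x, batch["token_mask"], rng)
        return self.head_tail_project(h, rng)
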