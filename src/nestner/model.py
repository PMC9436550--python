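"""Full model: encoder + biaffine span classifier + boundary head."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor
from .biaffine import BiaffineScorer
from .boundary import BoundaryHead
from .config import ModelConfig
from .corpus import Vocabulary
from .encoder import ContextualEmbedder, Encoder


class NestedNERModel(nn.Module):
    """Joint nested-NER model with a span-classification head and a
    boundary-detection head over a shared encoder."""

    def __init__(self, vocab: Vocabulary, cfg: ModelConfig,
                 rng: np.random.Generator | None = None,
                 word_vectors: np.ndarray | None = None,
                 contextual: ContextualEmbedder | None = None):
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.vocab = vocab
        self.encoder = Encoder(vocab, cfg, rng, word_vectors=word_vectors,
                               contextual=contextual)
        self.scorer = BiaffineScorer(cfg.mlp_size, vocab.labels.n_classes, rng,
                                     bias_augmented=cfg.biaffine_bias)
        self.boundary = BoundaryHead(cfg.mlp_size, rng,
                                     activation=cfg.boundary_activation)

    def forward(self, batch: dict, rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor]:
        """Span scores (B, N, N, C') and boundary logits (B, N, 2)."""
        s, e = self.encoder(batch, rng)
        return self.scorer(s, e), self.boundary(s, e)

    __call__ = forward

    # ---------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.state_dict())
        (directory / "vocab.json").write_text(self.vocab.to_json())
        self.cfg.to_yaml(directory / "config.yaml")

    @classmethod
    def load(cls, directory: str | Path,
             contextual: ContextualEmbedder | None = None) -> "NestedNERModel":
        directory = Path(directory)
        vocab = Vocabulary.from_json((directory / "vocab.json").read_text())
        cfg = ModelConfig.from_yaml(directory / "config.yaml")
        model = cls(vocab, cfg, contextual=contextual)
        with np.load(directory / "params.npz") as payload:
            model.load_state_dict({k: payload[k] for k in payload.files})
        return model
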