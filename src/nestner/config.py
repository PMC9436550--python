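"""Model and training configuration.

Defaults follow the recogniser's reference hyperparameters: a 3-layer BiLSTM
of total width 200 (dropout 0.4), head/tail MLPs of width 150 (dropout 0.2),
300-wide word vectors, 50-wide character embeddings convolved at widths 3-5,
dropout 0.5 on the concatenated embedding, Adam at learning rate 0.001.  The
mixing ratio `alpha` weights the boundary-detection loss in the joint
objective Multi_Loss = loss_b + alpha * loss_d.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    # embedding representation
    word_dim: int = 300
    char_dim: int = 50
    char_filter_widths: tuple[int, ...] = (3, 4, 5)
    char_filters: int = 50              # filters per width
    contextual_dim: int | None = None   # width of an optional external embedder
    emb_dropout: float = 0.5
    # shared feature representation
    lstm_size: int = 200                # total output width, half per direction
    lstm_layers: int = 3
    lstm_dropout: float = 0.4
    mlp_size: int = 150
    mlp_dropout: float = 0.2
    span_repr: str = "pre_softmax"      # or "post_softmax" (literal reading)
    # biaffine span classification
    biaffine_bias: bool = True          # bias-augment s, e inside the bilinear term
    max_span_length: int | None = None  # None: unbounded for N <= 64, else 16
    loss_reduction: str = "mean"        # or "sum" (literal summed objective)
    # boundary detection
    boundary_scheme: str = "inside"     # or "endpoints"
    boundary_activation: str = "relu"   # or "none" (literal affine head)
    gate_threshold: float = 0.5
    gating_enabled: bool = True
    # optimisation
    alpha: float = 1.0                  # boundary-loss mixing ratio, >= 0
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 20
    patience: int = 5
    target_f1: float | None = None      # optional early exit once dev F1 reached
    min_count: int = 1
    seed: int = 0
    rank_by: str = "score"              # overlap resolution ranking: score|probability

    def __post_init__(self):
        self.char_filter_widths = tuple(self.char_filter_widths)
        if self.alpha < 0:
            raise ValueError("alpha (boundary-loss mixing ratio) must be >= 0")
        if self.span_repr not in ("pre_softmax", "post_softmax"):
            raise ValueError("span_repr must be pre_softmax or post_softmax")
        if self.boundary_activation not in ("relu", "none"):
            raise ValueError("boundary_activation must be relu or none")
        if self.loss_reduction not in ("mean", "sum"):
            raise ValueError("loss_reduction must be mean or sum")
        if self.rank_by not in ("score", "probability"):
            raise ValueError("rank_by must be score or probability")

    def effective_max_span(self, sentence_length: int) -> int | None:
        """Span-length cap actually applied to a sentence: the configured cap,
        else unbounded for short sentences and 16 for long ones (the O(N^2)
        enumeration guard)."""
        if self.max_span_length is not None:
            return self.max_span_length
        return None if sentence_length <= 64 else 16

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Reduced widths for CPU-scale experiments on synthetic corpora.

        Dropout is scaled down with the capacity: the full-size rates are
        tuned against overfitting a 200/150-wide model on real corpora and
        mostly just slow optimisation of a 64/32-wide model on noise-free
        synthetic data.
        """
        base = dict(word_dim=50, char_dim=16, char_filters=8,
                    lstm_size=64, mlp_size=32,
                    emb_dropout=0.1, lstm_dropout=0.1, mlp_dropout=0.1)
        base.update(overrides)
        return cls(**base)

    # ------------------------------------------------------------- YAML I/O
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["char_filter_widths"] = list(self.char_filter_widths)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
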