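"""Shared fixtures.

The expensive end-to-end artefacts (a trained model on the default synthetic
corpus, and the paired single- vs multi-task ablation) are session-scoped so
the trainer tests and the acceptance tests share one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from nestner import (GeneratorConfig, ModelConfig, NestedNERModel,
                     build_vocab, generate_corpus, run_ablation, train)


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic study corpus: 2000 train / 200 test sentences,
    3 entity types, nesting probability 0.3, depth <= 2."""
    sentences = generate_corpus(GeneratorConfig(n_sentences=2200, seed=0))
    return sentences[:2000], sentences[2000:]


@pytest.fixture(scope="session")
def trained_model(default_corpus):
    """Joint model trained at reduced widths (BiLSTM 64, MLP 32) with
    alpha = 1 on the default corpus, up to 20 epochs."""
    train_sents, dev_sents = default_corpus
    cfg = ModelConfig.small(seed=0, epochs=20, alpha=1.0, target_f1=0.97)
    vocab = build_vocab(train_sents, min_count=cfg.min_count)
    model = NestedNERModel(vocab, cfg)
    log = train(model, train_sents, dev_sents, cfg)
    return model, cfg, log


@pytest.fixture(scope="session")
def ablation_report():
    """Paired alpha=0 vs alpha=1 comparison over 5 seeds on a reduced
    synthetic corpus (640 train / 100 test, 14 epochs)."""
    sentences = generate_corpus(GeneratorConfig(n_sentences=740, seed=11))
    cfg = ModelConfig.small(epochs=14, patience=14)
    return run_ablation(sentences[:640], sentences[640:], cfg,
                        alphas=(0.0, 1.0), seeds=(0, 1, 2, 3, 4))


@pytest.fixture
def tiny_cfg():
    """Millimetre-scale config for unit tests (fast, no dropout)."""
    return ModelConfig(word_dim=6, char_dim=4, char_filters=3,
                       char_filter_widths=(2, 3), lstm_size=8, lstm_layers=2,
                       mlp_size=5, emb_dropout=0.0, lstm_dropout=0.0,
                       mlp_dropout=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
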