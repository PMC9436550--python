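"""Experiment harnesses: the single-task vs multi-task ablation.

``run_ablation`` trains the model at several values of the boundary-loss
mixing ratio alpha under identical seeds and data splits.  alpha = 0 is the
single-task biaffine baseline; alpha > 0 mixes in the boundary-detection
loss.  The report carries paired per-seed held-out P/R/F1 and per-alpha
means, so the recall effect of the auxiliary task can be read off directly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ModelConfig
from .corpus import Sentence, build_vocab
from .metrics import evaluate_corpus
from .model import NestedNERModel
from .trainer import predict, train


def run_ablation(train_sents: list[Sentence], dev_sents: list[Sentence],
                 cfg: ModelConfig, alphas: tuple[float, ...] = (0.0, 1.0),
                 seeds: tuple[int, ...] = (0, 1, 2, 3, 4)) -> dict:
    vocab = build_vocab(train_sents, min_count=cfg.min_count)
    arms: dict[float, list[dict]] = {a: [] for a in alphas}
    for seed in seeds:
        for alpha in alphas:
            # alpha = 0 is the single-task biaffine baseline: its boundary
            # head is untrained, so boundary gating is disabled with it
            run_cfg = dataclasses.replace(cfg, alpha=alpha, seed=int(seed),
                                          gating_enabled=alpha > 0)
            model = NestedNERModel(vocab, run_cfg,
                                   rng=np.random.default_rng(int(seed)))
            train(model, train_sents, dev_sents, run_cfg)
            report = evaluate_corpus(predict(model, dev_sents, run_cfg), dev_sents)
            arms[alpha].append({"seed": int(seed), **report["overall"]})
    summary = {}
    for alpha, runs in arms.items():
        summary[alpha] = {
            "mean_P": float(np.mean([r["P"] for r in runs])),
            "mean_R": float(np.mean([r["R"] for r in runs])),
            "mean_F1": float(np.mean([r["F1"] for r in runs])),
            "runs": runs,
        }
    return {
        "alphas": list(alphas),
        "seeds": [int(s) for s in seeds],
        "arms": {str(a): summary[a] for a in alphas},
    }
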