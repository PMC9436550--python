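"""Train the joint model on a small synthetic corpus and score it.

The span classifier and the boundary detector are optimised together under
Multi_Loss = loss_b + alpha * loss_d; evaluation is entity-level exact-match
precision / recall / F1 on held-out sentences.  This is a scaled-down run
(2000 train sentences); expect two to three minutes on one CPU.
"""

import json

from nestner import (GeneratorConfig, ModelConfig, NestedNERModel,
                     build_vocab, evaluate_corpus, generate_corpus, predict,
                     train)

corpus = generate_corpus(GeneratorConfig(n_sentences=2200, seed=0))
train_sents, dev_sents = corpus[:2000], corpus[2000:]

cfg = ModelConfig.small(seed=0, epochs=20, alpha=1.0, target_f1=0.97)
vocab = build_vocab(train_sents)
model = NestedNERModel(vocab, cfg)

log = train(model, train_sents, dev_sents, cfg)
for record in log:
    print({k: round(v, 4) for k, v in record.items()})
# loss_b: span-classification cross-entropy over enumerated spans
# loss_d: boundary-detection cross-entropy over tokens
# dev_F1: held-out entity-level micro-F1 after each epoch

report = evaluate_corpus(predict(model, dev_sents, cfg), dev_sents)
print(json.dumps(report, indent=2))
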