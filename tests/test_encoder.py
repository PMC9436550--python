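"""Encoder: character CNN, embedding concatenation, BiLSTM, head/tail MLPs."""

from __future__ import annotations

import numpy as np
import pytest

from nestner import ModelConfig, NestedNERModel, Sentence, build_vocab
from nestner.corpus import EntityMention
from nestner.encoder import Encoder
from nestner.nn import CharCNN
from nestner.trainer import batch_losses, collate, multi_task_loss


def make_corpus():
    return [Sentence(["alpha", "bb", "c", "dddd", "ee"],
                     [EntityMention(1, 3, "X")]),
            Sentence(["bb", "alpha"], [EntityMention(0, 0, "Y")])]


@pytest.fixture
def setup(tiny_cfg):
    sents = make_corpus()
    vocab = build_vocab(sents)
    model = NestedNERModel(vocab, tiny_cfg)
    return sents, vocab, model


# ---------------------------------------------------------------- char CNN
def char_cnn_oracle(cnn: CharCNN, word_ids: np.ndarray, word_len: int) -> np.ndarray:
    """Explicit-loop reimplementation: per width, slide the filter over the
    character embeddings, ReLU, max over valid windows, concatenate."""
    emb = cnn.emb.table.data[word_ids]  # (Lc, dc)
    outs = []
    for w, lin in zip(cnn.widths, cnn.filters):
        eff = max(word_len, w)
        window_scores = []
        for k in range(eff - w + 1):
            window = emb[k:k + w].reshape(-1)
            window_scores.append(np.maximum(window @ lin.W.data + lin.b.data, 0.0))
        outs.append(np.max(window_scores, axis=0))
    return np.concatenate(outs)


def test_char_cnn_matches_hand_unrolled_convolution(setup, rng):
    sents, vocab, model = setup
    cnn = model.encoder.char_cnn
    for p in cnn.parameters():
        p.data = rng.normal(size=p.data.shape)
    batch = collate(sents, vocab, model.cfg)
    out = cnn(batch["char_ids"], batch["word_lens"]).numpy()
    for b, sent in enumerate(sents):
        for t, tok in enumerate(sent.tokens):
            expected = char_cnn_oracle(cnn, batch["char_ids"][b, t],
                                       batch["word_lens"][b, t])
            np.testing.assert_allclose(out[b, t], expected, atol=1e-10)


def test_char_cnn_single_character_word_is_defined(tiny_cfg):
    sents = [Sentence(["x"], [EntityMention(0, 0, "X")])]
    vocab = build_vocab(sents)
    model = NestedNERModel(vocab, tiny_cfg)
    batch = collate(sents, vocab, tiny_cfg)
    out = model.encoder.char_cnn(batch["char_ids"], batch["word_lens"]).numpy()
    assert out.shape == (1, 1, model.encoder.char_cnn.out_dim)
    assert np.all(np.isfinite(out))


def test_char_cnn_zero_filters_give_zero_vector(setup):
    sents, vocab, model = setup
    cnn = model.encoder.char_cnn
    for lin in cnn.filters:
        lin.W.data[:] = 0.0
        lin.b.data[:] = 0.0
    batch = collate(sents, vocab, model.cfg)
    np.testing.assert_array_equal(cnn(batch["char_ids"], batch["word_lens"]).numpy(), 0.0)


# ----------------------------------------------------------- concatenation
def test_embedding_width_is_sum_of_blocks(setup):
    sents, vocab, model = setup
    cfg = model.cfg
    batch = collate(sents, vocab, cfg)
    x = model.encoder.embed_tokens(batch)
    expected = cfg.word_dim + cfg.char_filters * len(cfg.char_filter_widths)
    assert x.shape[-1] == expected  # no contextual block when disabled


def test_unknown_token_uses_unknown_row(setup):
    sents, vocab, model = setup
    unseen = [Sentence(["zzzz"], []), Sentence(["qqqq"], [])]
    b1 = collate([unseen[0]], vocab, model.cfg)
    b2 = collate([unseen[1]], vocab, model.cfg)
    assert b1["word_ids"][0, 0] == b2["word_ids"][0, 0] == vocab.word_id("<unk>")


def test_embedding_equals_hand_concatenation(setup):
    sents, vocab, model = setup
    batch = collate(sents[:1], vocab, model.cfg)
    x = model.encoder.embed_tokens(batch).numpy()
    char_block = model.encoder.char_cnn(batch["char_ids"], batch["word_lens"]).numpy()
    word_block = model.encoder.word_emb.table.data[batch["word_ids"]]
    np.testing.assert_allclose(x, np.concatenate([char_block, word_block], axis=-1))


def test_contextual_embedder_wrong_length_is_fatal(tiny_cfg):
    import dataclasses
    sents = make_corpus()
    vocab = build_vocab(sents)
    cfg = dataclasses.replace(tiny_cfg, contextual_dim=7)
    bad = lambda tokens: np.zeros((len(tokens) + 1, 7))
    model = NestedNERModel(vocab, cfg, contextual=bad)
    batch = collate(sents, vocab, cfg)
    with pytest.raises(ValueError, match="contextual"):
        model.encoder.embed_tokens(batch)


def test_contextual_block_leads_the_concatenation(tiny_cfg):
    import dataclasses
    sents = make_corpus()
    vocab = build_vocab(sents)
    cfg = dataclasses.replace(tiny_cfg, contextual_dim=3)
    marker = lambda tokens: np.full((len(tokens), 3), 9.0)
    model = NestedNERModel(vocab, cfg, contextual=marker)
    batch = collate(sents[:1], vocab, cfg)
    x = model.encoder.embed_tokens(batch).numpy()
    np.testing.assert_array_equal(x[0, :, :3], 9.0)


# ------------------------------------------------------------------ BiLSTM
def test_evaluation_mode_is_deterministic(setup):
    sents, vocab, model = setup
    model.eval()
    batch = collate(sents, vocab, model.cfg)
    out1, _ = model(batch)
    out2, _ = model(batch)
    np.testing.assert_array_equal(out1.numpy(), out2.numpy())


def test_length_one_sequence_is_defined(tiny_cfg):
    sents = [Sentence(["solo"], [EntityMention(0, 0, "X")])]
    vocab = build_vocab(sents)
    model = NestedNERModel(vocab, tiny_cfg).eval()
    batch = collate(sents, vocab, tiny_cfg)
    s, e = model.encoder(batch)
    assert s.shape == (1, 1, tiny_cfg.mlp_size)
    assert np.all(np.isfinite(s.numpy())) and np.all(np.isfinite(e.numpy()))


def test_padded_batch_agrees_with_per_sentence_encoding(setup):
    """Batching invariance: padding must not leak into real positions."""
    sents, vocab, model = setup
    model.eval()
    batched = collate(sents, vocab, model.cfg)
    sb, eb = model.encoder(batched)
    for i, sent in enumerate(sents):
        single = collate([sent], vocab, model.cfg)
        ss, es = model.encoder(single)
        n = len(sent)
        np.testing.assert_allclose(sb.numpy()[i, :n], ss.numpy()[0], atol=1e-5)
        np.testing.assert_allclose(eb.numpy()[i, :n], es.numpy()[0], atol=1e-5)


# ----------------------------------------------------------- head/tail MLP
def test_zero_mlp_weights_give_zero_representations(setup):
    sents, vocab, model = setup
    enc = model.encoder
    for lin in (enc.mlp_s, enc.mlp_e):
        lin.W.data[:] = 0.0
        lin.b.data[:] = 0.0
    model.eval()
    batch = collate(sents, vocab, model.cfg)
    s, e = enc(batch)
    np.testing.assert_array_equal(s.numpy(), 0.0)
    np.testing.assert_array_equal(e.numpy(), 0.0)


def test_head_and_tail_representations_differ(setup):
    sents, vocab, model = setup
    model.eval()
    batch = collate(sents, vocab, model.cfg)
    s, e = model.encoder(batch)
    assert not np.allclose(s.numpy(), e.numpy())


def test_head_tail_projection_matches_hand_affine(tiny_cfg, rng):
    sents = [Sentence(["u", "v"], [EntityMention(0, 1, "X")])]
    vocab = build_vocab(sents)
    model = NestedNERModel(vocab, tiny_cfg).eval()
    enc = model.encoder
    batch = collate(sents, vocab, tiny_cfg)
    x = enc.embed_tokens(batch)
    h = enc.bilstm_encode(x, batch["token_mask"])
    s, e = enc.head_tail_project(h)
    h_np = h.numpy()
    np.testing.assert_allclose(
        s.numpy(), np.maximum(h_np @ enc.mlp_s.W.data + enc.mlp_s.b.data, 0.0),
        atol=1e-12)
    np.testing.assert_allclose(
        e.numpy(), np.maximum(h_np @ enc.mlp_e.W.data + enc.mlp_e.b.data, 0.0),
        atol=1e-12)


def test_post_softmax_option_normalises_representations(tiny_cfg):
    import dataclasses
    sents = make_corpus()
    vocab = build_vocab(sents)
    cfg = dataclasses.replace(tiny_cfg, span_repr="post_softmax")
    model = NestedNERModel(vocab, cfg).eval()
    batch = collate(sents[:1], vocab, cfg)
    s, _ = model.encoder(batch)
    np.testing.assert_allclose(s.numpy().sum(axis=-1), 1.0, atol=1e-9)


# ------------------------------------------------------------ gradient flow
def test_every_parameter_group_receives_gradient(setup, rng):
    sents, vocab, model = setup
    model.scorer.randomise()  # generic point in parameter space
    batch = collate(sents, vocab, model.cfg)
    loss_b, loss_d = batch_losses(model, batch, None)
    total = multi_task_loss(loss_b, loss_d, 1.0)
    model.zero_grad()
    total.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0.0), name
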