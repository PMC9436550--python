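"""Corpus readers/writers, boundary-label derivation and vocabularies."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestner import (EntityMention, GeneratorConfig, LabelSet, Sentence,
                     build_vocab, generate_corpus, make_boundary_labels,
                     read_conll, read_jsonl_spans, write_jsonl_spans)

# ------------------------------------------------------------------- CoNLL
CONLL_FIXTURE = """\
-DOCSTART- -X- -X- O

the O
colon B-DIS
cancer I-DIS

EU B-ORG
rejects O
German B-MISC
call O

Peter B-PER
Blackburn I-PER
BRUSSELS B-LOC

no O
entities O
here O

U.N. B-ORG
official O
Ekeus B-PER
heads O
Baghdad B-LOC

one B-A
two I-A
three B-A
four I-A
five I-A
"""

# independent hand enumeration of the fixture above (6 sentences, 12 runs)
CONLL_EXPECTED = [
    {(1, 2, "DIS")},
    {(0, 0, "ORG"), (2, 2, "MISC")},
    {(0, 1, "PER"), (2, 2, "LOC")},
    set(),
    {(0, 0, "ORG"), (2, 2, "PER"), (4, 4, "LOC")},
    {(0, 1, "A"), (2, 4, "A")},
]


def test_read_conll_matches_hand_parse(tmp_path):
    path = tmp_path / "fixture.conll"
    path.write_text(CONLL_FIXTURE)
    sentences = read_conll(path)
    assert len(sentences) == 6
    assert [{m.key for m in s.mentions} for s in sentences] == CONLL_EXPECTED


def test_read_conll_simple_bio_run(tmp_path):
    path = tmp_path / "s.conll"
    path.write_text("the O\ncolon B-DIS\ncancer I-DIS\n")
    [sent] = read_conll(path)
    assert {m.key for m in sent.mentions} == {(1, 2, "DIS")}


def test_read_conll_empty_file(tmp_path):
    path = tmp_path / "empty.conll"
    path.write_text("")
    assert read_conll(path) == []


def test_read_conll_repairs_stray_inside_tags(tmp_path, caplog):
    # I-X after O and I-X after B-Y are promoted to B-X with a warning
    path = tmp_path / "bad.conll"
    path.write_text("a O\nb I-X\nc B-Y\nd I-X\n")
    with caplog.at_level("WARNING"):
        [sent] = read_conll(path)
    assert {m.key for m in sent.mentions} == {(1, 1, "X"), (2, 2, "Y"), (3, 3, "X")}
    assert "repairing" in caplog.text


def test_read_conll_missing_file_is_fatal(tmp_path):
    with pytest.raises(OSError):
        read_conll(tmp_path / "absent.conll")


def test_read_conll_never_emits_invalid_mentions(tmp_path):
    path = tmp_path / "mixed.conll"
    path.write_text(CONLL_FIXTURE)
    for sent in read_conll(path):
        for m in sent.mentions:
            assert 0 <= m.start <= m.end < len(sent)


# -------------------------------------------------------------- span JSONL
def test_jsonl_single_mention(tmp_path):
    path = tmp_path / "one.jsonl"
    path.write_text('{"tokens":["mRNA"],"mentions":[{"start":0,"end":0,"label":"RNA"}]}\n')
    [sent] = read_jsonl_spans(path)
    assert sent.tokens == ["mRNA"]
    assert {m.key for m in sent.mentions} == {(0, 0, "RNA")}


def test_jsonl_nested_mentions_retained(tmp_path):
    path = tmp_path / "nested.jsonl"
    path.write_text('{"tokens":["a","b","c","d"],"mentions":'
                    '[{"start":0,"end":3,"label":"PER"},{"start":1,"end":2,"label":"ORG"}]}\n')
    [sent] = read_jsonl_spans(path)
    assert {m.key for m in sent.mentions} == {(0, 3, "PER"), (1, 2, "ORG")}


@pytest.mark.parametrize("line,message", [
    ('not json\n', "invalid JSON"),
    ('{"tokens":["a"],"mentions":[{"start":0,"end":5,"label":"X"}]}\n', "invalid"),
    ('{"tokens":["a","b"],"mentions":[{"start":1,"end":0,"label":"X"}]}\n', "invalid"),
])
def test_jsonl_malformed_records_are_fatal_with_line(tmp_path, line, message):
    path = tmp_path / "bad.jsonl"
    path.write_text(line)
    with pytest.raises(ValueError, match=f"{path.name}:1"):
        read_jsonl_spans(path)


def test_jsonl_round_trip_is_identity_on_synthetic_corpus(tmp_path):
    corpus = generate_corpus(GeneratorConfig(n_sentences=50, seed=5))
    path = tmp_path / "corpus.jsonl"
    write_jsonl_spans(corpus, path)
    back = read_jsonl_spans(path)
    assert len(back) == len(corpus)
    for a, b in zip(corpus, back):
        assert a.tokens == b.tokens
        assert {m.key for m in a.mentions} == {m.key for m in b.mentions}


def test_jsonl_write_is_deterministic_and_sorted(tmp_path):
    sent = Sentence(["a", "b", "c"], [EntityMention(1, 2, "Y"),
                                      EntityMention(0, 2, "X")])
    p1, p2 = tmp_path / "1.jsonl", tmp_path / "2.jsonl"
    write_jsonl_spans([sent], p1)
    write_jsonl_spans([sent], p2)
    assert p1.read_text() == p2.read_text()
    assert p1.read_text().index('"start": 0') < p1.read_text().index('"start": 1')


def test_jsonl_empty_corpus_writes_empty_file(tmp_path):
    path = tmp_path / "empty.jsonl"
    write_jsonl_spans([], path)
    assert path.read_text() == ""
    assert read_jsonl_spans(path) == []


def test_crossing_gold_mentions_flagged_not_rejected(caplog):
    with caplog.at_level("WARNING"):
        sent = Sentence(["a", "b", "c", "d"], [EntityMention(0, 2, "X"),
                                               EntityMention(1, 3, "Y")])
    assert len(sent.mentions) == 2
    assert "crossing" in caplog.text


# --------------------------------------------------------- boundary labels
@pytest.mark.parametrize("length,mentions,scheme,expected", [
    (5, [(1, 3, "X")], "inside", [0, 1, 1, 1, 0]),
    (5, [], "inside", [0, 0, 0, 0, 0]),
    (5, [(0, 4, "X"), (2, 2, "Y")], "inside", [1, 1, 1, 1, 1]),
    (5, [(0, 4, "X"), (2, 2, "Y")], "endpoints", [1, 0, 1, 0, 1]),
])
def test_boundary_labels_match_definition(length, mentions, scheme, expected):
    sent = Sentence([f"t{i}" for i in range(length)],
                    [EntityMention(*m) for m in mentions])
    np.testing.assert_array_equal(make_boundary_labels(sent, scheme), expected)


@settings(max_examples=60, derandomize=True)
@given(st.data())
def test_inside_labels_equal_interval_union_brute_force(data):
    n = data.draw(st.integers(3, 12))
    spans = data.draw(st.lists(st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)),
                               max_size=4))
    mentions = [EntityMention(min(a, b), max(a, b), f"T{k % 2}")
                for k, (a, b) in enumerate(spans)]
    mentions = list({m.key: m for m in mentions}.values())
    sent = Sentence([f"w{i}" for i in range(n)], mentions)
    labels = make_boundary_labels(sent, "inside")
    union = {t for m in mentions for t in range(m.start, m.end + 1)}
    assert labels.sum() == len(union)
    assert {i for i, v in enumerate(labels) if v} == union


# --------------------------------------------------------------- vocabulary
def test_vocab_min_count_maps_rare_words_to_unknown():
    sents = [Sentence(["a", "a", "a", "b"], [EntityMention(0, 0, "X")])]
    vocab = build_vocab(sents, min_count=2)
    assert vocab.word_id("a") != vocab.word_id("b")
    assert vocab.word_id("b") == vocab.word_id("<unk>")


def test_vocab_is_deterministic_and_complete():
    corpus = generate_corpus(GeneratorConfig(n_sentences=30, seed=2))
    v1, v2 = build_vocab(corpus), build_vocab(corpus)
    assert v1.word_to_index == v2.word_to_index
    assert v1.char_to_index == v2.char_to_index
    assert v1.labels == v2.labels
    assert set(v1.labels.entity_types) == {"T0", "T1", "T2"}
    assert v1.labels.n_classes == 4  # 3 types + non-entity


def test_vocab_empty_corpus_is_fatal():
    with pytest.raises(ValueError):
        build_vocab([])


def test_vocab_round_trips_through_json():
    corpus = generate_corpus(GeneratorConfig(n_sentences=10, seed=3))
    vocab = build_vocab(corpus)
    back = type(vocab).from_json(vocab.to_json())
    assert back.word_to_index == vocab.word_to_index
    assert back.char_to_index == vocab.char_to_index
    assert back.labels == vocab.labels


def test_label_set_rejects_collision_and_indexes_densely():
    with pytest.raises(ValueError):
        LabelSet(("X", "O"))
    ls = LabelSet(("A", "B"))
    assert [ls.index(x) for x in ("O", "A", "B")] == [0, 1, 2]
    assert [ls.label(i) for i in range(3)] == ["O", "A", "B"]
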