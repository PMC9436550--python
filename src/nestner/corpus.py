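"""Domain types and corpus I/O for nested named-entity recognition.

A corpus is a sequence of :class:`Sentence` objects: a token list plus a set
of typed mentions given as 0-based, inclusive token spans.  Mentions may nest
(one properly contained in another) and may share boundaries; crossing
mentions — partial overlap without containment — are accepted from gold data
with a warning but are never produced by the decoder or the generator.

Supported formats: CoNLL-2003 columns (flat BIO tags, read only) and a
span-JSONL dialect carrying nested annotations (read/write), one sentence per
line::

    {"tokens": ["the", "colon", "cancer"],
     "mentions": [{"start": 1, "end": 2, "label": "DIS"},
                  {"start": 1, "end": 1, "label": "ANAT"}]}
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntityMention:
    """A typed token span; `end` is inclusive.  `score` is set on predictions."""

    start: int
    end: int
    label: str
    score: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.label)

    def contains(self, other: "EntityMention") -> bool:
        return self.start <= other.start and other.end <= self.end

    def crosses(self, other: "EntityMention") -> bool:
        """Partial overlap without containment (forbidden in predictions)."""
        a, b = self, other
        return (a.start < b.start <= a.end < b.end) or (b.start < a.start <= b.end < a.end)


@dataclass
class Sentence:
    tokens: list[str]
    mentions: list[EntityMention] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.tokens)
        seen: set[tuple[int, int, str]] = set()
        for m in self.mentions:
            if m.end >= n:
                raise ValueError(f"mention {m.key} out of range for length {n}")
            if m.key in seen:
                raise ValueError(f"duplicate gold mention {m.key}")
            seen.add(m.key)
        for i, a in enumerate(self.mentions):
            for b in self.mentions[i + 1:]:
                if a.crosses(b):
                    logger.warning("crossing gold mentions %s / %s", a.key, b.key)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class LabelSet:
    """Ordered entity types plus a reserved non-entity class at index 0."""

    entity_types: tuple[str, ...]
    non_entity: str = "O"

    def __post_init__(self):
        if not self.entity_types:
            raise ValueError("at least one entity type is required")
        if self.non_entity in self.entity_types:
            raise ValueError("non-entity name collides with an entity type")

    @property
    def n_classes(self) -> int:
        """C' = number of entity types + the non-entity class."""
        return len(self.entity_types) + 1

    def index(self, label: str) -> int:
        if label == self.non_entity:
            return 0
        return self.entity_types.index(label) + 1

    def label(self, index: int) -> str:
        return self.non_entity if index == 0 else self.entity_types[index - 1]


PAD, UNK = "<pad>", "<unk>"


@dataclass
class Vocabulary:
    word_to_index: dict[str, int]
    char_to_index: dict[str, int]
    labels: LabelSet

    def word_id(self, token: str) -> int:
        return self.word_to_index.get(token, self.word_to_index[UNK])

    def char_id(self, ch: str) -> int:
        return self.char_to_index.get(ch, self.char_to_index[UNK])

    @property
    def n_words(self) -> int:
        return len(self.word_to_index)

    @property
    def n_chars(self) -> int:
        return len(self.char_to_index)

    def to_json(self) -> str:
        return json.dumps({
            "words": sorted(self.word_to_index, key=self.word_to_index.get),
            "chars": sorted(self.char_to_index, key=self.char_to_index.get),
            "entity_types": list(self.labels.entity_types),
            "non_entity": self.labels.non_entity,
        })

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        d = json.loads(payload)
        return cls(
            word_to_index={w: i for i, w in enumerate(d["words"])},
            char_to_index={c: i for i, c in enumerate(d["chars"])},
            labels=LabelSet(tuple(d["entity_types"]), d["non_entity"]),
        )


def build_vocab(sentences: Sequence[Sentence], min_count: int = 1) -> Vocabulary:
    """Frequency-then-lexicographic vocabulary with reserved pad/unk slots.

    Words rarer than `min_count` map to the unknown index; the character and
    label maps are always complete.
    """
    if not sentences:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    word_counts: Counter[str] = Counter()
    char_counts: Counter[str] = Counter()
    label_names: set[str] = set()
    for sent in sentences:
        word_counts.update(sent.tokens)
        for tok in sent.tokens:
            char_counts.update(tok)
        label_names.update(m.label for m in sent.mentions)

    def ordered(counts: Counter[str], threshold: int) -> list[str]:
        kept = [w for w, c in counts.items() if c >= threshold]
        return sorted(kept, key=lambda w: (-counts[w], w))

    words = [PAD, UNK] + ordered(word_counts, min_count)
    chars = [PAD, UNK] + ordered(char_counts, 1)
    return Vocabulary(
        word_to_index={w: i for i, w in enumerate(words)},
        char_to_index={c: i for i, c in enumerate(chars)},
        labels=LabelSet(tuple(sorted(label_names))),
    )


# --------------------------------------------------------------- CoNLL read
def read_conll(path: str | Path) -> list[Sentence]:
    """Read CoNLL-2003 column format: token in the first column, BIO tag in
    the last, blank lines separating sentences, ``-DOCSTART-`` lines dropped.

    Malformed transitions (``I-X`` after ``O`` or after ``B-Y`` with Y != X)
    are repaired by promoting the stray ``I-X`` to ``B-X``, with a warning.
    """
    path = Path(path)
    sentences: list[Sentence] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush():
        if tokens:
            sentences.append(Sentence(list(tokens), _bio_to_mentions(tags)))
            tokens.clear()
            tags.clear()

    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split()
            if cols[0] == "-DOCSTART-":
                flush()
                continue
            tokens.append(cols[0])
            tags.append(cols[-1])
    flush()
    return sentences


def _bio_to_mentions(tags: list[str]) -> list[EntityMention]:
    mentions: list[EntityMention] = []
    start: int | None = None
    label: str | None = None

    def close(end: int):
        nonlocal start, label
        if start is not None:
            mentions.append(EntityMention(start, end, label))
        start, label = None, None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i - 1)
            continue
        prefix, _, name = tag.partition("-")
        if prefix == "I" and label == name:
            continue
        if prefix == "I":
            logger.warning("repairing stray I-%s at position %d (treated as B-%s)",
                           name, i, name)
        close(i - 1)
        start, label = i, name
    close(len(tags) - 1)
    return mentions


# --------------------------------------------------------------- span JSONL
def read_jsonl_spans(path: str | Path) -> list[Sentence]:
    """Read the span-JSONL dialect (one sentence object per line)."""
    path = Path(path)
    sentences: list[Sentence] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            tokens = record["tokens"]
            mentions = []
            for m in record.get("mentions", []):
                if m["end"] < m["start"] or m["start"] < 0 or m["end"] >= len(tokens):
                    raise ValueError(
                        f"{path}:{lineno}: span ({m['start']}, {m['end']}) "
                        f"invalid for sentence of length {len(tokens)}")
                mentions.append(EntityMention(m["start"], m["end"], m["label"]))
            sentences.append(Sentence(tokens, mentions))
    return sentences


def write_jsonl_spans(sentences: Iterable[Sentence], path: str | Path) -> None:
    """Inverse of :func:`read_jsonl_spans`; mentions are written sorted by
    (start, end, label) so output is deterministic."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in sentences:
            record = {
                "tokens": sent.tokens,
                "mentions": [
                    {"start": m.start, "end": m.end, "label": m.label}
                    for m in sorted(sent.mentions, key=lambda m: m.key)
                ],
            }
            fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------- boundary labels
def make_boundary_labels(sentence: Sentence, scheme: str = "inside") -> np.ndarray:
    """Per-token boundary targets for the auxiliary task, as 0 (O) / 1 (I).

    ``inside``: a token is I iff it lies inside (the union of) any mention.
    ``endpoints``: a token is I iff it is the start or end of some mention.
    """
    labels = np.zeros(len(sentence), dtype=np.int64)
    if scheme == "inside":
        for m in sentence.mentions:
            labels[m.start:m.end + 1] = 1
    elif scheme == "endpoints":
        for m in sentence.mentions:
            labels[m.start] = 1
            labels[m.end] = 1
    else:
        raise ValueError(f"unknown boundary scheme {scheme!r}")
    return labels
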