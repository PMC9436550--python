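"""Pretrained word-vector loading (plain-text format, one token per line).

Each line is ``token v1 v2 ... vd``.  Tokens present in the vocabulary get
their pretrained row; everything else (including pad/unk) keeps a small
random initialisation, so the table is usable whether or not coverage is
complete.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .corpus import Vocabulary


def load_word_vectors(path: str | Path, vocab: Vocabulary, dim: int,
                      seed: int = 0) -> np.ndarray:
    """Build a (n_words, dim) embedding table seeded from a text vector file."""
    rng = np.random.default_rng(seed)
    table = rng.uniform(-0.1, 0.1, size=(vocab.n_words, dim))
    n_loaded = 0
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip().split(" ")
            if len(parts) < 2:
                continue
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ValueError(
                    f"vector for {token!r} has width {len(values)}, expected {dim}")
            idx = vocab.word_to_index.get(token)
            if idx is not None:
                table[idx] = np.asarray(values, dtype=np.float64)
                n_loaded += 1
    if n_loaded == 0:
        raise ValueError("no vectors in the file matched the vocabulary")
    return table
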