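"""Synthetic nested-entity corpora with a learnable surface signal.

Sentences are drawn over a closed vocabulary of filler tokens.  Each mention
opens with a *trigger* token unique to its entity type and closes with a
matching *terminator* token, so both the type and the extent of every
mention are decodable from the surface form alone — a model with no
pretrained knowledge can reach near-perfect scores, and end-to-end tests
measure the architecture rather than world knowledge.  (The terminator plays
the role the head noun plays in real nested mentions such as "colon cancer",
whose last token closes the outer entity.)

Top-level mentions are placed without overlap; with probability ``p_nest`` a
mention receives one strictly interior child (recursively, to ``max_depth``).
A child occupies [parent.start + 1, parent.end - 1], so parents keep their
trigger and terminator and generated corpora never contain crossing
mentions.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import EntityMention, Sentence


@dataclass
class GeneratorConfig:
    n_sentences: int = 2000
    sentence_length: tuple[int, int] = (8, 16)   # inclusive range
    n_types: int = 3
    triggers_per_type: int = 4
    filler_vocab: int = 200
    p_nest: float = 0.3
    max_depth: int = 2
    mention_length: tuple[int, int] = (4, 7)      # top-level mentions, inclusive
    max_mentions: int = 3                         # top-level placement attempts
    seed: int = 0
    type_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0.0 <= self.p_nest <= 1.0:
            raise ValueError("p_nest must lie in [0, 1]")
        if self.mention_length[0] > self.sentence_length[0]:
            raise ValueError("mention length exceeds the shortest sentence")
        if self.mention_length[0] < 2:
            raise ValueError("mentions need at least a trigger and a terminator")
        if not self.type_names:
            self.type_names = tuple(f"T{k}" for k in range(self.n_types))
        if len(self.type_names) != self.n_types:
            raise ValueError("type_names must have n_types entries")

    def triggers(self) -> dict[str, list[str]]:
        """Disjoint per-type mention-opening token lists."""
        return {name: [f"trg_{name}_{j}" for j in range(self.triggers_per_type)]
                for name in self.type_names}

    def terminators(self) -> dict[str, list[str]]:
        """Disjoint per-type mention-closing token lists."""
        return {name: [f"fin_{name}_{j}" for j in range(self.triggers_per_type)]
                for name in self.type_names}


def generate_corpus(config: GeneratorConfig) -> list[Sentence]:
    rng = np.random.default_rng(config.seed)
    lexicon = (config.triggers(), config.terminators())
    fillers = [f"w{j}" for j in range(config.filler_vocab)]
    sentences = []
    for _ in range(config.n_sentences):
        sentences.append(_generate_sentence(config, rng, lexicon, fillers))
    return sentences


def _generate_sentence(cfg: GeneratorConfig, rng: np.random.Generator,
                       lexicon: tuple[dict, dict],
                       fillers: list[str]) -> Sentence:
    length = int(rng.integers(cfg.sentence_length[0], cfg.sentence_length[1] + 1))
    tokens = [fillers[i] for i in rng.integers(0, len(fillers), size=length)]
    mentions: list[EntityMention] = []
    occupied: list[tuple[int, int]] = []
    n_top = int(rng.integers(1, cfg.max_mentions + 1))
    for _ in range(n_top):
        m_len = int(rng.integers(cfg.mention_length[0],
                                 min(cfg.mention_length[1], length) + 1))
        placed = _place_interval(rng, length, m_len, occupied)
        if placed is None:
            continue
        start, end = placed
        occupied.append((start, end))
        _emit_mention(cfg, rng, lexicon, tokens, mentions, start, end, depth=1)
    return Sentence(tokens, mentions)


def _place_interval(rng: np.random.Generator, length: int, m_len: int,
                    occupied: list[tuple[int, int]],
                    tries: int = 8) -> tuple[int, int] | None:
    for _ in range(tries):
        start = int(rng.integers(0, length - m_len + 1))
        end = start + m_len - 1
        if all(end < s or e < start for s, e in occupied):
            return start, end
    return None


def _emit_mention(cfg: GeneratorConfig, rng: np.random.Generator,
                  lexicon: tuple[dict, dict], tokens: list[str],
                  mentions: list[EntityMention], start: int, end: int,
                  depth: int) -> None:
    triggers, terminators = lexicon
    type_name = cfg.type_names[int(rng.integers(0, cfg.n_types))]
    tokens[start] = triggers[type_name][int(rng.integers(0, cfg.triggers_per_type))]
    tokens[end] = terminators[type_name][int(rng.integers(0, cfg.triggers_per_type))]
    mentions.append(EntityMention(start, end, type_name))
    # a child lives strictly inside [start+1, end-1]: the parent keeps both
    # its trigger and its terminator, and the child carries its own pair
    can_nest = depth < cfg.max_depth and (end - start - 1) >= 2
    if can_nest and rng.random() < cfg.p_nest:
        child_len = int(rng.integers(2, end - start))
        child_start = int(rng.integers(start + 1, end - child_len + 1))
        _emit_mention(cfg, rng, lexicon, tokens, mentions,
                      child_start, child_start + child_len - 1, depth + 1)


# ------------------------------------------------------------------- stats
def mention_depths(sentence: Sentence) -> dict[EntityMention, int]:
    """Depth of each mention: 1 + the number of mentions properly containing it."""
    depths = {}
    for m in sentence.mentions:
        depth = 1 + sum(1 for other in sentence.mentions
                        if other.key != m.key and other.contains(m))
        depths[m] = depth
    return depths


def corpus_stats(sentences: Sequence[Sentence]) -> dict:
    """Summary statistics: mention count, nesting-depth histogram, type
    distribution, and the fraction of depth-1 mentions with a nested child."""
    n_mentions = 0
    depth_hist: Counter[int] = Counter()
    type_dist: Counter[str] = Counter()
    n_top = 0
    n_top_with_child = 0
    for sent in sentences:
        depths = mention_depths(sent)
        n_mentions += len(sent.mentions)
        for m, d in depths.items():
            depth_hist[d] += 1
            type_dist[m.label] += 1
            if d == 1:
                n_top += 1
                if any(m.contains(o) and o.key != m.key for o in sent.mentions):
                    n_top_with_child += 1
    return {
        "n_sentences": len(sentences),
        "n_mentions": n_mentions,
        "depth_histogram": dict(sorted(depth_hist.items())),
        "type_distribution": dict(sorted(type_dist.items())),
        "top_level_mentions": n_top,
        "nesting_rate": (n_top_with_child / n_top) if n_top else 0.0,
    }
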