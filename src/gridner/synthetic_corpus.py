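"""Synthetic biomedical-style corpus generation.

Real BioNER corpora have a few statistical traits that matter for a word-pair
grid model: sentences are fairly long while entities are sparse, many
mentions span several tokens, and chemical names often surface as
alphanumeric/hyphen patterns ("CD-832") that the tokenizer breaks into
several tokens. The generator reproduces those traits over a deterministic
synthetic vocabulary so the full pipeline can be exercised end to end.

Filler (non-entity) tokens are drawn from a Zipf-skewed vocabulary; entity
surface forms come from a disjoint lexicon, so a model can in principle solve
the toy task from lexical identity alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import EntityMention, LabeledSentence

__all__ = ["SynthesisConfig", "generate_corpus"]

_CONSONANTS = list("bcdfghklmnprstvz")
_VOWELS = list("aeiou")


@dataclass
class SynthesisConfig:
    """Knobs of the generator; defaults emulate a sparse-entity corpus with
    moderately long sentences and a mix of single- and multi-token mentions."""

    n_sentences: int = 200
    mean_length: float = 12.0
    max_length: int = 20
    entity_density: float = 1.2  # expected mentions per sentence
    multi_token_fraction: float = 0.5
    entity_types: tuple[str, ...] = ("Chemical",)
    chemical_like_fraction: float = 0.3
    filler_vocab_size: int = 400
    entity_vocab_size: int = 60
    seed: int = 0

    def __post_init__(self):
        for name in ("multi_token_fraction", "chemical_like_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.entity_density < 0:
            raise ValueError("entity_density must be >= 0")
        if not self.entity_types:
            raise ValueError("at least one entity type is required")


def _pseudoword(rng: np.random.Generator, n_syll: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
    )


def _make_vocab(rng: np.random.Generator, size: int, n_syll: tuple[int, int]) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < size:
        w = _pseudoword(rng, int(rng.integers(n_syll[0], n_syll[1] + 1)))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _chemical_like(rng: np.random.Generator) -> list[str]:
    """An alphanumeric-hyphen chemical pattern that splits into >= 2 tokens,
    e.g. ['XQ', '-', '417'] — the multi-token "CD-832" shape."""
    letters = "".join(rng.choice(list("ABCDEFGHKLMNPQRSTVXZ"), size=int(rng.integers(1, 4))))
    digits = str(int(rng.integers(10, 10000)))
    return [letters, "-", digits]


def generate_corpus(config: SynthesisConfig) -> list[LabeledSentence]:
    """Generate a corpus deterministically from ``config.seed``.

    Raises ``RuntimeError`` if the requested entity density cannot be placed
    without overlaps after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    filler = _make_vocab(rng, config.filler_vocab_size, (2, 4))
    # entity lexicon disjoint from filler: longer pseudowords, distinct draw
    entity_words = [w + rng.choice(list("xz")) for w in
                    _make_vocab(rng, config.entity_vocab_size, (3, 5))]
    # Zipf-like filler frequencies
    ranks = np.arange(1, len(filler) + 1, dtype=float)
    filler_p = (1.0 / ranks) / np.sum(1.0 / ranks)

    sentences: list[LabeledSentence] = []
    total_requested = 0
    total_failed = 0
    for si in range(config.n_sentences):
        n = int(np.clip(rng.poisson(config.mean_length), 3, config.max_length))
        tokens = [str(w) for w in rng.choice(filler, size=n, p=filler_p)]
        n_mentions = int(rng.poisson(config.entity_density))
        placed: list[EntityMention] = []
        occupied = np.zeros(n, dtype=bool)
        failures = 0
        for _ in range(n_mentions):
            ok = False
            for _attempt in range(100):
                etype = str(rng.choice(config.entity_types))
                if rng.random() < config.chemical_like_fraction:
                    surface = _chemical_like(rng)
                elif rng.random() < config.multi_token_fraction:
                    k = int(rng.integers(2, 4))
                    surface = [str(rng.choice(entity_words)) for _ in range(k)]
                else:
                    surface = [str(rng.choice(entity_words))]
                k = len(surface)
                if k > n:
                    continue
                start = int(rng.integers(0, n - k + 1))
                if occupied[start : start + k].any():
                    continue
                occupied[start : start + k] = True
                tokens[start : start + k] = surface
                placed.append(EntityMention(start, start + k - 1, etype))
                ok = True
                break
            if not ok:
                failures += 1
        total_requested += n_mentions
        total_failed += failures
        sentences.append(LabeledSentence(tokens, frozenset(placed), id=f"syn{si}"))
    if total_requested and total_failed > 0.2 * total_requested:
        raise RuntimeError(
            f"entity_density too high: {total_failed}/{total_requested} mention "
            "placements failed after bounded retries"
        )
    return sentences
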