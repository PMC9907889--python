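import numpy as np
import pytest

from gridner.corpus_io import EntityMention, LabeledSentence, WordPieceTokenizer
from gridner.grid_codec import RelationSet
from gridner.prefix_encoder import EncoderConfig
from gridner.synthetic_corpus import SynthesisConfig, generate_corpus


@pytest.fixture(scope="session")
def cd832_sentence() -> LabeledSentence:
    """The canonical 3-token multi-piece chemical mention."""
    return LabeledSentence(
        ["CD", "-", "832"], {EntityMention(0, 2, "Chemical")}, id="cd832"
    )


@pytest.fixture(scope="session")
def small_corpus() -> list[LabeledSentence]:
    return generate_corpus(SynthesisConfig(n_sentences=40, seed=11))


@pytest.fixture(scope="session")
def small_tokenizer(small_corpus) -> WordPieceTokenizer:
    return WordPieceTokenizer.from_corpus(small_corpus)


@pytest.fixture(scope="session")
def small_rset(small_corpus) -> RelationSet:
    return RelationSet.from_corpus(small_corpus)


@pytest.fixture
def toy_encoder_config() -> EncoderConfig:
    return EncoderConfig(
        layers=2, heads=2, hidden_dim=16, prefix_length=2, word_dim=16,
        vocab_size=64, max_positions=64,
    )


def random_flat_sentence(rng: np.random.Generator, max_n: int = 30,
                         types=("A", "B")) -> LabeledSentence:
    """A random token sequence with random non-overlapping mentions."""
    n = int(rng.integers(1, max_n + 1))
    tokens = [f"w{int(rng.integers(0, 50))}" for _ in range(n)]
    mentions = set()
    occupied = np.zeros(n, dtype=bool)
    for _ in range(int(rng.integers(0, 4))):
        k = int(rng.integers(1, 4))
        if k > n:
            continue
        s = int(rng.integers(0, n - k + 1))
        if occupied[s : s + k].any():
            continue
        occupied[s : s + k] = True
        mentions.add(EntityMention(s, s + k - 1, str(rng.choice(types))))
    return LabeledSentence(tokens, mentions)
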