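"""Corpus input/output: CoNLL-style BIO files, span/tag conversion and
word-to-subword alignment.

The unit of all I/O is the :class:`LabeledSentence` — a token sequence plus a
set of flat (non-overlapping, non-nested) entity mentions with 0-based,
end-inclusive word coordinates. Tag files use the two-column CoNLL layout
(token first, tag last, blank line between sentences); a JSON-lines
alternative stores mentions explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "EntityMention",
    "LabeledSentence",
    "SubwordAlignment",
    "WordPieceTokenizer",
    "spans_from_bio",
    "bio_from_spans",
    "read_conll",
    "write_conll",
    "read_jsonl",
    "write_jsonl",
    "build_subword_alignment",
]


@dataclass(frozen=True, order=True)
class EntityMention:
    """A flat entity mention: word indices ``start..end`` inclusive."""

    start: int
    end: int
    etype: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"mention start {self.start} > end {self.end}")
        if self.start < 0:
            raise ValueError("mention start must be >= 0")

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class LabeledSentence:
    tokens: list[str]
    mentions: frozenset[EntityMention] = field(default_factory=frozenset)
    id: str = ""

    def __post_init__(self):
        self.tokens = [t for t in self.tokens if t]
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")
        self.mentions = frozenset(self.mentions)
        n = len(self.tokens)
        ms = sorted(self.mentions)
        for m in ms:
            if m.end >= n:
                raise ValueError(f"mention {m} out of range for length {n}")
        for a, b in zip(ms, ms[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping mentions {a} and {b} (flat NER only)")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def entity_types(self) -> set[str]:
        return {m.etype for m in self.mentions}


# ---------------------------------------------------------------------------
# BIO <-> spans
# ---------------------------------------------------------------------------

_VALID_PREFIXES = {"O", "B", "I", "E", "S"}


def _parse_tag(tag: str, lineno: int | None = None) -> tuple[str, str | None]:
    if tag == "O":
        return "O", None
    if len(tag) >= 2 and tag[1] == "-" and tag[0] in _VALID_PREFIXES:
        return tag[0], tag[2:]
    where = f" at line {lineno}" if lineno is not None else ""
    raise ValueError(f"malformed tag {tag!r}{where}")


def spans_from_bio(tags: Sequence[str], repairs: list | None = None) -> frozenset[EntityMention]:
    """Convert BIO/BIOES tags to mentions.

    A dangling ``I-X`` (after ``O``, sentence start, or ``I-Y``/``B-Y`` of a
    different type) is repaired as ``B-X``; repairs are appended to the
    optional ``repairs`` list so callers can count and log them.
    """
    mentions: set[EntityMention] = set()
    start: int | None = None
    cur_type: str | None = None

    def close(end: int):
        nonlocal start, cur_type
        if start is not None:
            mentions.add(EntityMention(start, end, cur_type))
        start, cur_type = None, None

    for i, tag in enumerate(tags):
        prefix, etype = _parse_tag(tag)
        if prefix == "O":
            close(i - 1)
        elif prefix in ("B", "S"):
            close(i - 1)
            start, cur_type = i, etype
            if prefix == "S":
                close(i)
        elif prefix in ("I", "E"):
            if start is None or etype != cur_type:
                if repairs is not None:
                    repairs.append((i, tag))
                close(i - 1)
                start, cur_type = i, etype
            if prefix == "E":
                close(i)
    close(len(tags) - 1)
    return frozenset(mentions)


def bio_from_spans(mentions: Iterable[EntityMention], n: int) -> list[str]:
    """Render flat mentions as BIO tags of length ``n``."""
    tags = ["O"] * n
    ms = sorted(mentions)
    for a, b in zip(ms, ms[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping mentions {a} and {b}")
    for m in ms:
        if m.end >= n:
            raise ValueError(f"mention {m} out of range for n={n}")
        tags[m.start] = f"B-{m.etype}"
        for k in range(m.start + 1, m.end + 1):
            tags[k] = f"I-{m.etype}"
    return tags


# ---------------------------------------------------------------------------
# CoNLL files
# ---------------------------------------------------------------------------

def read_conll(path: str | Path, scheme: str = "BIO") -> list[LabeledSentence]:
    """Read a two-column CoNLL file (token first column, tag last column;
    extra middle columns ignored; blank line separates sentences)."""
    if scheme not in ("BIO", "BIOES"):
        raise ValueError(f"unknown scheme {scheme!r}")
    sentences: list[LabeledSentence] = []
    tokens: list[str] = []
    tags: list[str] = []
    n_repairs = 0

    def flush(sid: int):
        nonlocal tokens, tags, n_repairs
        if tokens:
            repairs: list = []
            mentions = spans_from_bio(tags, repairs)
            n_repairs += len(repairs)
            sentences.append(LabeledSentence(tokens, mentions, id=f"s{sid}"))
        tokens, tags = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(len(sentences))
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 columns, got {cols!r}")
            _parse_tag(cols[-1], lineno)  # malformed tags are hard errors
            tokens.append(cols[0])
            tags.append(cols[-1])
    flush(len(sentences))
    if n_repairs:
        logger.warning("repaired %d dangling I- tags as B- while reading %s", n_repairs, path)
    return sentences


def write_conll(sentences: Iterable[LabeledSentence], path: str | Path):
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            for tok, tag in zip(s.tokens, bio_from_spans(s.mentions, len(s))):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def read_jsonl(path: str | Path) -> list[LabeledSentence]:
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            rec = json.loads(line)
            mentions = frozenset(
                EntityMention(int(a), int(b), str(t)) for a, b, t in rec.get("mentions", [])
            )
            sentences.append(LabeledSentence(rec["tokens"], mentions, id=rec.get("id", f"s{i}")))
    return sentences


def write_jsonl(sentences: Iterable[LabeledSentence], path: str | Path):
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            rec = {
                "id": s.id,
                "tokens": s.tokens,
                "mentions": sorted([m.start, m.end, m.etype] for m in s.mentions),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Subword tokenization and word/piece alignment
# ---------------------------------------------------------------------------

@dataclass
class SubwordAlignment:
    """Maps each word to its contiguous range of encoder positions.

    ``ranges[w] = (lo, hi)`` with ``hi`` inclusive, indices into the piece
    sequence *including* the boundary specials; positions 0 and len-1 are the
    start/end special tokens.
    """

    piece_ids: list[int]
    ranges: list[tuple[int, int]]
    n_pieces: int
    has_start_special: bool = True
    has_end_special: bool = True

    def __post_init__(self):
        expected = 1 if self.has_start_special else 0
        for lo, hi in self.ranges:
            if lo != expected or hi < lo:
                raise ValueError("alignment ranges must be contiguous and ordered")
            expected = hi + 1
        tail = expected + (1 if self.has_end_special else 0)
        if tail != self.n_pieces:
            raise ValueError("alignment ranges must cover every non-special position")


class WordPieceTokenizer:
    """Greedy longest-match subword tokenizer with ``##`` continuations.

    The vocabulary is built from a corpus: special tokens, every whole word,
    and every character (plus its ``##`` continuation form) so any string of
    known characters tokenizes; unknown characters map to ``[UNK]``.
    """

    START, END, UNK, PAD = "[CLS]", "[SEP]", "[UNK]", "[PAD]"

    def __init__(self, vocab: dict[str, int]):
        for sp in (self.PAD, self.START, self.END, self.UNK):
            if sp not in vocab:
                raise ValueError(f"vocabulary missing special token {sp}")
        self.vocab = vocab
        self.inv_vocab = {i: t for t, i in vocab.items()}

    @classmethod
    def from_corpus(cls, sentences: Iterable[LabeledSentence],
                    max_word_vocab: int = 20000) -> "WordPieceTokenizer":
        from collections import Counter

        counts: Counter[str] = Counter()
        chars: set[str] = set()
        for s in sentences:
            for t in s.tokens:
                counts[t] += 1
                chars.update(t)
        vocab: dict[str, int] = {}
        for sp in (cls.PAD, cls.START, cls.END, cls.UNK):
            vocab[sp] = len(vocab)
        for ch in sorted(chars):
            for form in (ch, "##" + ch):
                if form not in vocab:
                    vocab[form] = len(vocab)
        for word, _ in counts.most_common(max_word_vocab):
            if word not in vocab:
                vocab[word] = len(vocab)
        return cls(vocab)

    def tokenize_word(self, word: str) -> list[str]:
        if not word:
            raise ValueError("cannot tokenize an empty word")
        pieces: list[str] = []
        pos = 0
        while pos < len(word):
            end = len(word)
            piece = None
            while end > pos:
                cand = word[pos:end] if pos == 0 else "##" + word[pos:end]
                if cand in self.vocab:
                    piece = cand
                    break
                end -= 1
            if piece is None:
                piece = self.UNK
                end = pos + 1
            pieces.append(piece)
            pos = end
        return pieces

    def piece_id(self, piece: str) -> int:
        return self.vocab.get(piece, self.vocab[self.UNK])

    def __len__(self) -> int:
        return len(self.vocab)

    def save(self, path: str | Path):
        Path(path).write_text(json.dumps(self.vocab, ensure_ascii=False), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "WordPieceTokenizer":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))


def build_subword_alignment(sentence: LabeledSentence,
                            tokenizer: WordPieceTokenizer) -> SubwordAlignment:
    """Tokenize a sentence to pieces, prepend/append the boundary specials and
    record each word's piece range."""
    piece_ids = [tokenizer.piece_id(tokenizer.START)]
    ranges: list[tuple[int, int]] = []
    for word in sentence.tokens:
        pieces = tokenizer.tokenize_word(word)
        lo = len(piece_ids)
        piece_ids.extend(tokenizer.piece_id(p) for p in pieces)
        ranges.append((lo, len(piece_ids) - 1))
    piece_ids.append(tokenizer.piece_id(tokenizer.END))
    return SubwordAlignment(piece_ids=piece_ids, ranges=ranges, n_pieces=len(piece_ids))
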