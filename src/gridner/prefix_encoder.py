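"""Prefix-guided transformer encoder, subword pooling and BiLSTM contextualizer.

Every attention layer carries a bank of trainable key/value prefix vectors:
P extra key/value rows per head that real tokens may attend to but that never
act as queries. The post-softmax attention weight matrix of each head is
therefore L x (L+P); the layer output applies those weights to the value rows
including the value prefixes. Attention maps from a configurable subset of
layers ("guided layers") are exposed for the attention-guidance loss.

Piece-level encoder states are pooled to word level using the word/piece
alignment (elementwise max by default) and contextualized by a bidirectional
LSTM into the word representations that feed the pair grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import MLP, Embedding, LayerNorm, Linear, Module, Parameter, normal_init
from .corpus_io import SubwordAlignment

__all__ = [
    "EncoderConfig",
    "PrefixBank",
    "AttentionMapStack",
    "PrefixTransformerEncoder",
    "BiLSTM",
    "init_prefix_bank",
    "prefix_self_attention",
    "pool_subwords",
]


@dataclass
class EncoderConfig:
    layers: int = 2
    heads: int = 2
    hidden_dim: int = 32
    ffn_dim: int | None = None  # defaults to 2 * hidden_dim
    prefix_length: int = 4
    guided_layers: tuple[int, ...] | None = None  # 1-based; default last 4 (clipped)
    vocab_size: int = 128
    max_positions: int = 128
    word_dim: int = 64  # BiLSTM output dimension d_h
    pooling: str = "max"  # subword -> word pooling: "max" or "mean"
    checkpoint: str = "random"

    def __post_init__(self):
        if self.hidden_dim % self.heads != 0:
            raise ValueError("hidden_dim must be divisible by heads")
        if self.prefix_length < 0:
            raise ValueError("prefix_length must be >= 0")
        if self.word_dim % 2 != 0:
            raise ValueError("word_dim must be even (half per LSTM direction)")
        if self.ffn_dim is None:
            self.ffn_dim = 2 * self.hidden_dim
        if self.guided_layers is None:
            lo = max(1, self.layers - 3)
            self.guided_layers = tuple(range(lo, self.layers + 1))
        else:
            self.guided_layers = tuple(self.guided_layers)
        bad = [g for g in self.guided_layers if not 1 <= g <= self.layers]
        if bad:
            raise ValueError(f"guided_layers out of range: {bad}")
        if self.pooling not in ("max", "mean"):
            raise ValueError("pooling must be 'max' or 'mean'")


class PrefixBank(Module):
    """Per-layer trainable key/value prefixes, each (P, d); independent
    across layers and never used as queries."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        P, d = config.prefix_length, config.hidden_dim
        self.keys = [Parameter(normal_init(rng, (P, d))) for _ in range(config.layers)]
        self.values = [Parameter(normal_init(rng, (P, d))) for _ in range(config.layers)]
        self.prefix_length = P


def init_prefix_bank(config: EncoderConfig, seed: int) -> PrefixBank:
    return PrefixBank(config, np.random.default_rng(seed))


@dataclass
class AttentionMapStack:
    """Attention maps from the guided layers, layer-major head-minor.

    ``maps`` has shape (batch, n_guided_layers * heads, L, L + P) and stays in
    the autodiff graph so the guidance loss can shape the maps through
    training. ``query_mask``/``key_mask`` flag real (non-pad) positions; the
    P prefix columns are always valid keys.
    """

    maps: Tensor
    L: int
    P: int
    query_mask: np.ndarray  # (batch, L)

    @property
    def n_heads(self) -> int:
        return self.maps.shape[1]


def _broadcast_prefix(phi: Tensor, B: int, h: int, P: int, dh: int) -> Tensor:
    """(P, d) prefix -> (B, h, P, dh) with gradient-aware broadcasting."""
    per_head = phi.reshape(P, h, dh).transpose(1, 0, 2).reshape(1, h, P, dh)
    return per_head + Tensor(np.zeros((B, 1, 1, 1)))


def prefix_self_attention(
    H: Tensor,
    wq: Linear,
    wk: Linear,
    wv: Linear,
    phi_k: Parameter,
    phi_v: Parameter,
    heads: int,
    key_mask: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """One multi-head attention pass with key/value prefixes.

    Returns the per-head context (B, L, d) *before* the output projection and
    the post-softmax attention maps (B, heads, L, L+P). Padded key positions
    receive -inf logits; prefix columns are always attendable.
    """
    B, L, d = H.shape
    dh = d // heads
    P = phi_k.shape[0] if phi_k is not None else 0

    def split(x: Tensor) -> Tensor:  # (B, L, d) -> (B, h, L, dh)
        return x.reshape(B, L, heads, dh).transpose(0, 2, 1, 3)

    Q, K, V = split(wq(H)), split(wk(H)), split(wv(H))
    if P > 0:
        K = concat([K, _broadcast_prefix(phi_k, B, heads, P, dh)], axis=2)
        V = concat([V, _broadcast_prefix(phi_v, B, heads, P, dh)], axis=2)
    logits = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    full_key_mask = np.concatenate(
        [key_mask, np.ones((B, P), dtype=key_mask.dtype)], axis=1
    )
    attn = logits.masked_softmax(full_key_mask[:, None, None, :], axis=-1)
    ctx = (attn @ V).transpose(0, 2, 1, 3).reshape(B, L, d)
    return ctx, attn


class _TransformerLayer(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d = config.hidden_dim
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ffn_in = Linear(d, config.ffn_dim, rng)
        self.ffn_out = Linear(config.ffn_dim, d, rng)
        self.heads = config.heads

    def __call__(self, H: Tensor, phi_k, phi_v, key_mask) -> tuple[Tensor, Tensor]:
        ctx, attn = prefix_self_attention(
            H, self.wq, self.wk, self.wv, phi_k, phi_v, self.heads, key_mask
        )
        H = self.ln1(H + self.wo(ctx))
        H = self.ln2(H + self.ffn_out(self.ffn_in(H).gelu()))
        return H, attn


class PrefixTransformerEncoder(Module):
    """Compact randomly initialized transformer encoder with per-layer
    prefix banks; structurally the shape of a BERT-family encoder so real
    checkpoints could be mapped in, but trained from scratch here."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        d = config.hidden_dim
        self.tok_emb = Embedding(config.vocab_size, d, rng)
        self.pos_emb = Embedding(config.max_positions, d, rng)
        self.seg_emb = Embedding(2, d, rng)
        self.emb_ln = LayerNorm(d)
        self.layers = [_TransformerLayer(config, rng) for _ in range(config.layers)]
        self.prefix = PrefixBank(config, rng)

    def __call__(self, piece_ids: np.ndarray, piece_mask: np.ndarray
                 ) -> tuple[Tensor, AttentionMapStack]:
        """Encode padded piece-id batch (B, L) with validity mask (B, L).

        Returns per-piece states (B, L, d) and the guided-layer attention
        stack (maps collected post-softmax, before the value product).
        """
        B, L = piece_ids.shape
        if L > self.config.max_positions:
            raise ValueError(
                f"sequence length {L} exceeds positional capacity "
                f"{self.config.max_positions}; truncate the input"
            )
        pos = np.broadcast_to(np.arange(L), (B, L))
        seg = np.zeros((B, L), dtype=np.intp)
        H = self.emb_ln(self.tok_emb(piece_ids) + self.pos_emb(pos) + self.seg_emb(seg))
        guided = set(self.config.guided_layers)
        collected: list[Tensor] = []
        for li, layer in enumerate(self.layers, start=1):
            H, attn = layer(H, self.prefix.keys[li - 1], self.prefix.values[li - 1],
                            piece_mask)
            if li in guided:
                collected.append(attn)
        maps = concat(collected, axis=1) if len(collected) > 1 else collected[0]
        stack = AttentionMapStack(
            maps=maps, L=L, P=self.config.prefix_length, query_mask=piece_mask
        )
        return H, stack


def pool_subwords(
    piece_states: Tensor,
    alignments: list[SubwordAlignment],
    n_words: np.ndarray,
    mode: str = "max",
) -> Tensor:
    """Pool piece vectors to one vector per word (batch-padded to max word
    count). Boundary specials are excluded; padded word slots are zero."""
    B, L, d = piece_states.shape
    N = int(n_words.max())
    data = piece_states.data
    out = np.zeros((B, N, d))
    for b, al in enumerate(alignments):
        for w, (lo, hi) in enumerate(al.ranges):
            seg = data[b, lo : hi + 1]
            out[b, w] = seg.max(axis=0) if mode == "max" else seg.mean(axis=0)

    def backward(g):
        if not piece_states.requires_grad:
            return
        full = np.zeros_like(data)
        for b, al in enumerate(alignments):
            for w, (lo, hi) in enumerate(al.ranges):
                if mode == "max":
                    seg = data[b, lo : hi + 1]
                    sel = seg.argmax(axis=0)
                    full[b, lo + sel, np.arange(d)] += g[b, w]
                else:
                    full[b, lo : hi + 1] += g[b, w] / (hi - lo + 1)
        piece_states._accum(full)

    return piece_states._make(out, (piece_states,), backward)


class BiLSTM(Module):
    """Bidirectional LSTM over word vectors; concatenated hidden states give
    the d_h-dimensional word representations."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        if d_out % 2 != 0:
            raise ValueError("BiLSTM output dim must be even")
        self.hd = d_out // 2
        self.fwd = _LSTMDirection(d_in, self.hd, rng)
        self.bwd = _LSTMDirection(d_in, self.hd, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        out_f = self.fwd.run(x, mask, reverse=False)
        out_b = self.bwd.run(x, mask, reverse=True)
        return concat([out_f, out_b], axis=-1)


class _LSTMDirection(Module):
    def __init__(self, d_in: int, hd: int, rng: np.random.Generator):
        from ._nn import xavier_init

        self.W = Parameter(xavier_init(rng, d_in, 4 * hd))
        self.U = Parameter(xavier_init(rng, hd, 4 * hd))
        self.b = Parameter(np.zeros(4 * hd))
        self.hd = hd

    def run(self, x: Tensor, mask: np.ndarray, reverse: bool) -> Tensor:
        from ._autodiff import stack as t_stack

        B, N, _ = x.shape
        hd = self.hd
        h = Tensor(np.zeros((B, hd)))
        c = Tensor(np.zeros((B, hd)))
        order = range(N - 1, -1, -1) if reverse else range(N)
        outs: dict[int, Tensor] = {}
        for t in order:
            xt = x[:, t, :]
            m = Tensor(mask[:, t : t + 1].astype(float))
            gates = xt @ self.W + h @ self.U + self.b
            i = gates[:, 0 * hd : 1 * hd].sigmoid()
            f = gates[:, 1 * hd : 2 * hd].sigmoid()
            g = gates[:, 2 * hd : 3 * hd].tanh()
            o = gates[:, 3 * hd : 4 * hd].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            # padded steps carry state through unchanged
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
            outs[t] = h * m
        return t_stack([outs[t] for t in range(N)], axis=1)
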