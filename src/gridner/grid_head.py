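"""Word-pair grid construction and per-cell relation classification.

For word representations h_1..h_n, every ordered pair (i, j) gets a cell
vector via conditional layer normalization (CLN): h_j is layer-normalized,
but the gain and bias are generated from the *conditioning* word h_i, so the
cell encodes "j in the context of i". Cells are enriched with bucketed
signed-distance embeddings and a region embedding (upper triangle / diagonal
/ lower triangle), projected by a perceptron to the grid channel width,
refined by a single shape-preserving dilated 3x3 convolution with GELU, and
classified per cell into the relation set by an MLP + softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import MLP, Embedding, Linear, Module, Parameter, normal_init
from .grid_codec import RelationGrid, RelationSet

__all__ = [
    "CLNParams",
    "PredictionGrid",
    "conditional_layer_norm",
    "cln_grid",
    "distance_bucket",
    "GridHead",
    "bioner_loss",
]

N_DISTANCE_BUCKETS = 19  # signed log buckets: 9 negative, zero, 9 positive
REGION_UPPER, REGION_DIAGONAL, REGION_LOWER = 0, 1, 2


class CLNParams(Module):
    """Maps generating the conditional gain and bias from the condition
    vector. Initialized so the gain is 1 and the bias 0: CLN then starts as
    plain layer normalization."""

    def __init__(self, d_h: int, eps: float = 1e-5):
        self.w_alpha = Parameter(np.zeros((d_h, d_h)))
        self.b_alpha = Parameter(np.ones(d_h))
        self.w_beta = Parameter(np.zeros((d_h, d_h)))
        self.b_beta = Parameter(np.zeros(d_h))
        self.eps = eps


def _standardize(h: Tensor, eps: float) -> Tensor:
    mu = h.mean(axis=-1, keepdims=True)
    centered = h - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    return centered / (var + eps) ** 0.5


def conditional_layer_norm(h_i: Tensor, h_j: Tensor, params: CLNParams) -> Tensor:
    """CLN of one pair: gamma(h_i) * standardize(h_j) + lambda(h_i)."""
    gamma = h_i @ params.w_alpha + params.b_alpha
    lam = h_i @ params.w_beta + params.b_beta
    return gamma * _standardize(h_j, params.eps) + lam


def cln_grid(h: Tensor, params: CLNParams) -> Tensor:
    """All-pairs CLN: (B, N, d_h) word states -> (B, N, N, d_h) pair grid,
    cell (i, j) conditioned on word i, normalizing word j."""
    B, N, d = h.shape
    gamma = (h @ params.w_alpha + params.b_alpha).reshape(B, N, 1, d)
    lam = (h @ params.w_beta + params.b_beta).reshape(B, N, 1, d)
    normed = _standardize(h, params.eps).reshape(B, 1, N, d)
    return gamma * normed + lam


def distance_bucket(offset: int | np.ndarray) -> np.ndarray:
    """Bucket signed offsets j - i logarithmically; clamped at |offset|>64."""
    off = np.asarray(offset)
    mag = np.abs(off)
    b = np.zeros_like(mag)
    edges = [1, 2, 3, 5, 9, 17, 33, 65]  # lower bounds of magnitude buckets 1..8
    for k, lo in enumerate(edges, start=1):
        b = np.where(mag >= lo, k, b)
    return (9 + np.sign(off) * b).astype(np.intp)


def _region_indices(N: int) -> np.ndarray:
    i = np.arange(N)[:, None]
    j = np.arange(N)[None, :]
    reg = np.full((N, N), REGION_UPPER, dtype=np.intp)
    reg[i == j] = REGION_DIAGONAL
    reg[(i > j)] = REGION_LOWER
    return reg


@dataclass
class PredictionGrid:
    """Per-cell relation distributions for a batch of padded sentences."""

    logits: Tensor  # (B, N, N, |R|)
    probs: Tensor  # (B, N, N, |R|)
    n_words: np.ndarray  # (B,)

    def argmax_grid(self, b: int, rset: RelationSet) -> RelationGrid:
        n = int(self.n_words[b])
        cells = self.probs.data[b, :n, :n].argmax(axis=-1)
        return RelationGrid(n, cells)

    def thw_prob_grid(self, b: int, rset: RelationSet) -> np.ndarray:
        """Max THW-type probability per cell (used for overlap resolution)."""
        n = int(self.n_words[b])
        return self.probs.data[b, :n, :n, 2:].max(axis=-1)


class GridHead(Module):
    def __init__(
        self,
        d_h: int,
        n_relations: int,
        rng: np.random.Generator,
        d_g: int = 128,
        d_dist: int = 20,
        d_region: int = 20,
        kernel_size: int = 3,
        dilation: int = 2,
    ):
        self.cln = CLNParams(d_h)
        self.dist_emb = Embedding(N_DISTANCE_BUCKETS, d_dist, rng)
        self.region_emb = Embedding(3, d_region, rng)
        self.hybrid_mlp = MLP(d_h + d_dist + d_region, d_g, rng)
        self.conv_kernel = Parameter(
            normal_init(rng, (kernel_size, kernel_size, d_g, d_g), std=0.05)
        )
        self.conv_bias = Parameter(np.zeros(d_g))
        self.classifier = MLP(d_g, n_relations, rng, d_hidden=d_g)
        self.dilation = dilation

    def build_hybrid_grid(self, W: Tensor) -> Tensor:
        """Concatenate the CLN grid with distance and region embeddings and
        project to the grid channel width (Eq.-style MLP)."""
        B, N, _, _ = W.shape
        offsets = np.arange(N)[None, :] - np.arange(N)[:, None]  # j - i
        dist_idx = distance_bucket(offsets)
        D = self.dist_emb(np.broadcast_to(dist_idx, (B, N, N)))
        R = self.region_emb(np.broadcast_to(_region_indices(N), (B, N, N)))
        return self.hybrid_mlp(concat([W, D, R], axis=-1))

    def dilated_refine(self, G: Tensor) -> Tensor:
        return (G.conv2d(self.conv_kernel, dilation=self.dilation) + self.conv_bias).gelu()

    def classify_pairs(self, S: Tensor, n_words: np.ndarray) -> PredictionGrid:
        logits = self.classifier(S)
        return PredictionGrid(logits=logits, probs=logits.softmax(axis=-1), n_words=n_words)

    def __call__(self, h: Tensor, n_words: np.ndarray) -> PredictionGrid:
        W = cln_grid(h, self.cln)
        G = self.build_hybrid_grid(W)
        S = self.dilated_refine(G)
        return self.classify_pairs(S, n_words)


def bioner_loss(pred: PredictionGrid, gold_cells: np.ndarray) -> Tensor:
    """Mean per-cell cross-entropy against one-hot gold relation labels.

    Each sentence contributes the sum of cell cross-entropies over its own
    n x n valid cells divided by n^2; the batch loss is the sentence mean.
    """
    logits = pred.logits
    B, N, _, K = logits.shape
    if gold_cells.shape != (B, N, N):
        raise ValueError(f"gold grid shape {gold_cells.shape} != {(B, N, N)}")
    cmax = Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = ((logits - cmax).exp().sum(axis=-1, keepdims=True)).log() + cmax
    logp = logits - lse
    onehot = np.zeros((B, N, N, K))
    np.put_along_axis(onehot, gold_cells[..., None].astype(np.intp), 1.0, axis=-1)
    mask = np.zeros((B, N, N, 1))
    weights = np.zeros((B, 1, 1, 1))
    for b, n in enumerate(pred.n_words):
        n = int(n)
        mask[b, :n, :n] = 1.0
        weights[b] = 1.0 / (n * n)
    per_cell = logp * Tensor(onehot * mask * weights)
    return -(per_cell.sum()) * (1.0 / B)
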