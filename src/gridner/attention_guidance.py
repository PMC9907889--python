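"""Attention-map instance discrimination: the guidance loss that pushes the
attention heads of the guided layers apart.

Each guided head's post-softmax map is pooled into a "received attention"
vector: for every key position, the total attention it collects over all
(real) query rows. Two pooled views exist per head — ``o`` over the L token
columns only and ``p`` over all L+P columns including the prefixes. Rows are
L2-normalized onto the unit sphere and every head is treated as its own class
in a non-parametric softmax with temperature τ; the negative log-likelihood
of each head being assigned to itself is the discrimination loss. The fused
guidance loss is the plain mean of the losses on the o-view and the p-view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, concat
from .prefix_encoder import AttentionMapStack

__all__ = [
    "HeadVectorMatrices",
    "GuidanceLossValue",
    "pool_received_attention",
    "assemble_head_matrices",
    "instance_discrimination_loss",
    "fused_guidance_loss",
    "cosine_similarity_matrix",
    "mean_offdiagonal_cosine",
]


@dataclass
class HeadVectorMatrices:
    """Row-normalized pooled head vectors for one sentence.

    ``O``: (m, L) over token columns; ``P``: (m, L+P) including prefix
    columns; m = number of guided heads (layer-major, head-minor order).
    """

    O: Tensor
    P: Tensor
    tau: float = 2.0


@dataclass
class GuidanceLossValue:
    loss_o: Tensor
    loss_p: Tensor

    @property
    def loss_guidance(self) -> Tensor:
        return (self.loss_p + self.loss_o) * 0.5


def pool_received_attention(A: Tensor, query_mask: np.ndarray | None = None
                            ) -> tuple[Tensor, Tensor]:
    """Column-sum one attention map over its (unmasked) query rows.

    ``A`` is (..., L, L+P); returns ``o`` (..., L) and ``p`` (..., L+P) where
    ``p[k]`` is the attention key position k received. Masked query rows
    contribute nothing.
    """
    A = as_tensor(A)
    L = A.shape[-2]
    if query_mask is not None:
        m = np.asarray(query_mask, dtype=float)
        A = A * Tensor(m[..., :, None])
    p = A.sum(axis=-2)
    o = p[..., :L]
    return o, p


def _normalize_rows(M: Tensor) -> Tensor:
    """L2-normalize rows to exactly unit norm; an all-zero row (fully masked
    map) is replaced by the uniform unit vector."""
    k = M.shape[-1]
    sumsq = (M**2).sum(axis=-1, keepdims=True)
    zero = (sumsq.data <= 0.0).astype(float)
    if zero.any():
        import logging

        logging.getLogger(__name__).warning(
            "replaced %d zero pooled-attention rows by uniform vectors",
            int(zero.sum()),
        )
        M = M + Tensor(zero / np.sqrt(k))
        sumsq = (M**2).sum(axis=-1, keepdims=True)
    return M / sumsq**0.5


def assemble_head_matrices(stack: AttentionMapStack, tau: float = 2.0,
                           batch_index: int | None = None
                           ) -> HeadVectorMatrices | list[HeadVectorMatrices]:
    """Pool every guided head of an :class:`AttentionMapStack` and assemble
    the row-normalized O/P matrices (one pair per sentence)."""
    maps = stack.maps  # (B, m, L, L+P)
    B = maps.shape[0]
    out: list[HeadVectorMatrices] = []
    indices = range(B) if batch_index is None else [batch_index]
    for b in indices:
        o, p = pool_received_attention(maps[b], stack.query_mask[b][None, :])
        out.append(HeadVectorMatrices(O=_normalize_rows(o), P=_normalize_rows(p), tau=tau))
    if batch_index is not None:
        return out[0]
    return out


def instance_discrimination_loss(M: Tensor, tau: float = 2.0) -> Tensor:
    """Non-parametric softmax self-classification loss over unit-norm rows.

    loss = -Σ_i log[ exp(m_i·m_i/τ) / Σ_j exp(m_j·m_i/τ) ].
    """
    M = as_tensor(M)
    m = M.shape[0]
    if m < 2:
        raise ValueError("instance discrimination needs at least 2 rows")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    S = (M @ M.transpose()) * (1.0 / tau)  # (m, m), symmetric
    cmax = Tensor(S.data.max(axis=0, keepdims=True))  # detached shift
    lse = ((S - cmax).exp().sum(axis=0)).log() + cmax.reshape(m)
    diag = (S * Tensor(np.eye(m))).sum(axis=0)
    return (lse - diag).sum()


def fused_guidance_loss(hv: HeadVectorMatrices | list[HeadVectorMatrices]) -> GuidanceLossValue:
    """Fused guidance loss; for a batch (list of per-sentence matrices) the
    o/p losses are each averaged over sentences before fusing."""
    items = hv if isinstance(hv, list) else [hv]
    lo = [instance_discrimination_loss(h.O, h.tau) for h in items]
    lp = [instance_discrimination_loss(h.P, h.tau) for h in items]

    def avg(xs):
        total = xs[0]
        for x in xs[1:]:
            total = total + x
        return total * (1.0 / len(xs))

    return GuidanceLossValue(loss_o=avg(lo), loss_p=avg(lp))


def cosine_similarity_matrix(M: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities of rows (diagnostics export)."""
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = M / norms
    return U @ U.T


def mean_offdiagonal_cosine(M: np.ndarray) -> float:
    C = cosine_similarity_matrix(M)
    m = C.shape[0]
    if m < 2:
        return 0.0
    off = C[~np.eye(m, dtype=bool)]
    return float(off.mean())
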