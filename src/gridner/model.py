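"""End-to-end word-pair grid NER model.

Pipeline per batch: subword pieces -> prefix-guided transformer (collecting
guided-layer attention maps) -> max-pool pieces to words -> BiLSTM -> CLN
pair grid -> hybrid distance/region enrichment -> dilated convolution ->
per-cell relation classifier. Training minimizes the grid cross-entropy plus
alpha times the attention-map discrimination loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from ._nn import Module
from .attention_guidance import (
    GuidanceLossValue,
    assemble_head_matrices,
    fused_guidance_loss,
)
from .corpus_io import (
    LabeledSentence,
    SubwordAlignment,
    WordPieceTokenizer,
    build_subword_alignment,
)
from .grid_codec import RelationSet, encode_grid
from .grid_head import GridHead, PredictionGrid, bioner_loss
from .prefix_encoder import (
    AttentionMapStack,
    BiLSTM,
    EncoderConfig,
    PrefixTransformerEncoder,
    pool_subwords,
)

__all__ = ["Batch", "ForwardResult", "WordPairGridModel", "make_batch"]


@dataclass
class Batch:
    sentences: list[LabeledSentence]
    piece_ids: np.ndarray  # (B, Lp) padded
    piece_mask: np.ndarray  # (B, Lp)
    alignments: list[SubwordAlignment]
    n_words: np.ndarray  # (B,)
    gold_cells: np.ndarray | None  # (B, N, N) padded with NONE


def make_batch(
    sentences: list[LabeledSentence],
    tokenizer: WordPieceTokenizer,
    rset: RelationSet | None = None,
) -> Batch:
    """Pad a list of sentences to the batch maxima (the per-batch L of the
    attention maps is the longest piece sequence in the batch)."""
    alignments = [build_subword_alignment(s, tokenizer) for s in sentences]
    B = len(sentences)
    Lp = max(len(a.piece_ids) for a in alignments)
    pad_id = tokenizer.piece_id(tokenizer.PAD)
    piece_ids = np.full((B, Lp), pad_id, dtype=np.intp)
    piece_mask = np.zeros((B, Lp), dtype=np.float64)
    for b, a in enumerate(alignments):
        piece_ids[b, : len(a.piece_ids)] = a.piece_ids
        piece_mask[b, : len(a.piece_ids)] = 1.0
    n_words = np.array([len(s) for s in sentences], dtype=np.intp)
    gold = None
    if rset is not None:
        N = int(n_words.max())
        gold = np.zeros((B, N, N), dtype=np.int64)
        for b, s in enumerate(sentences):
            g = encode_grid(s, rset)
            gold[b, : g.n, : g.n] = g.cells
    return Batch(sentences, piece_ids, piece_mask, alignments, n_words, gold)


@dataclass
class ForwardResult:
    prediction: PredictionGrid
    attention: AttentionMapStack
    loss_bioner: Tensor | None = None
    guidance: GuidanceLossValue | None = None

    def total_loss(self, alpha: float) -> Tensor:
        total = self.loss_bioner
        if alpha and self.guidance is not None:
            total = total + alpha * self.guidance.loss_guidance
        return total


class WordPairGridModel(Module):
    def __init__(
        self,
        encoder_config: EncoderConfig,
        rset: RelationSet,
        d_g: int = 128,
        d_dist: int = 20,
        d_region: int = 20,
        kernel_size: int = 3,
        dilation: int = 2,
        tau: float = 2.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed + 1)
        self.encoder = PrefixTransformerEncoder(encoder_config, seed=seed)
        self.bilstm = BiLSTM(encoder_config.hidden_dim, encoder_config.word_dim, rng)
        self.head = GridHead(
            encoder_config.word_dim,
            len(rset),
            rng,
            d_g=d_g,
            d_dist=d_dist,
            d_region=d_region,
            kernel_size=kernel_size,
            dilation=dilation,
        )
        self.rset = rset
        self.tau = tau
        self.config = encoder_config

    def forward(self, batch: Batch, compute_loss: bool = True,
                compute_guidance: bool = True) -> ForwardResult:
        piece_states, stack = self.encoder(batch.piece_ids, batch.piece_mask)
        words = pool_subwords(
            piece_states, batch.alignments, batch.n_words, mode=self.config.pooling
        )
        word_mask = np.zeros(words.shape[:2])
        for b, n in enumerate(batch.n_words):
            word_mask[b, : int(n)] = 1.0
        h = self.bilstm(words, word_mask)
        prediction = self.head(h, batch.n_words)
        result = ForwardResult(prediction=prediction, attention=stack)
        if compute_loss and batch.gold_cells is not None:
            result.loss_bioner = bioner_loss(prediction, batch.gold_cells)
        if compute_guidance:
            result.guidance = fused_guidance_loss(assemble_head_matrices(stack, tau=self.tau))
        return result

    __call__ = forward

    def predict_mentions(self, batch: Batch):
        """Argmax grids decoded to mentions (THW probabilities resolve
        overlapping candidates)."""
        from ._autodiff import no_grad
        from .grid_codec import decode_grid

        with no_grad():
            result = self.forward(batch, compute_loss=False, compute_guidance=False)
        out = []
        for b in range(len(batch.sentences)):
            grid = result.prediction.argmax_grid(b, self.rset)
            probs = result.prediction.thw_prob_grid(b, self.rset)
            out.append(decode_grid(grid, self.rset, thw_probs=probs))
        return out
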