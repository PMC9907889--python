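"""Training loop, entity-level evaluation and prediction.

Training minimizes ``Loss_total = Loss_grid + alpha * Loss_guidance`` with
AdamW under a linear warm-up/decay schedule; the batch padding length L is
the longest sentence in each batch. Evaluation is micro-averaged exact-match
entity-level precision/recall/F1: a predicted mention counts as a true
positive only when both its span and its type equal a gold mention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._nn import AdamW, linear_warmup_decay
from .corpus_io import EntityMention, LabeledSentence, WordPieceTokenizer
from .grid_codec import RelationSet
from .model import Batch, WordPairGridModel, make_batch
from .prefix_encoder import EncoderConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalResult",
    "TrainedModel",
    "total_loss",
    "evaluate_entities",
    "summarize_runs",
    "train_model",
    "predict",
]


@dataclass
class TrainConfig:
    alpha: float = 0.01  # guidance weight; grid-searched over {1e-1..1e-4}
    tau: float = 2.0
    batch_size: int = 8
    lr: float = 1e-3
    weight_decay: float = 0.1
    warmup_frac: float = 0.1
    epochs: int = 30
    seed: int = 0
    shuffle: bool = True
    backbone_lr_scale: float = 1.0  # separate group for encoder parameters
    log_every: int = 0  # epochs between log lines; 0 = silent

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0 (0 disables guidance)")


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @staticmethod
    def from_counts(tp: int, fp: int, fn: int) -> "EvalResult":
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return EvalResult(round(p, 2), round(r, 2), round(f1, 2), tp, fp, fn)


def total_loss(loss_bioner: float, loss_guidance: float, alpha: float) -> float:
    """Joint objective: grid loss plus alpha-weighted guidance loss."""
    return loss_bioner + alpha * loss_guidance


def evaluate_entities(
    pred: Sequence[Iterable[EntityMention]],
    gold: Sequence[Iterable[EntityMention]],
) -> EvalResult:
    """Micro-averaged exact-match entity-level P/R/F1 over aligned sentences."""
    if len(pred) != len(gold):
        raise ValueError("pred and gold must align sentence-by-sentence")
    tp = fp = fn = 0
    for p_sent, g_sent in zip(pred, gold):
        ps, gs = set(p_sent), set(g_sent)
        tp += len(ps & gs)
        fp += len(ps - gs)
        fn += len(gs - ps)
    return EvalResult.from_counts(tp, fp, fn)


def summarize_runs(f1_scores: Sequence[float]) -> dict[str, float]:
    """Mean/std/max F1 over repeated seeds, reported to 2 decimals."""
    arr = np.asarray(f1_scores, dtype=float)
    return {
        "mean": round(float(arr.mean()), 2),
        "std": round(float(arr.std()), 2),
        "max": round(float(arr.max()), 2),
        "runs": len(arr),
    }


@dataclass
class TrainedModel:
    model: WordPairGridModel
    tokenizer: WordPieceTokenizer
    rset: RelationSet
    history: list[dict] = field(default_factory=list)

    def save(self, path: str):
        """Checkpoint: npz holding all weights (prefix banks included) plus
        the config, vocabulary and entity types as JSON metadata."""
        import json
        from dataclasses import asdict

        head = self.model.head
        meta = {
            "encoder": asdict(self.model.config),
            "entity_types": self.rset.entity_types,
            "vocab": self.tokenizer.vocab,
            "tau": self.model.tau,
            "d_g": head.conv_kernel.shape[-1],
            "d_dist": head.dist_emb.weight.shape[1],
            "d_region": head.region_emb.weight.shape[1],
            "kernel_size": head.conv_kernel.shape[0],
            "dilation": head.dilation,
        }
        arrays = {f"param:{k}": v for k, v in self.model.state_dict().items()}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        enc = meta["encoder"]
        enc["guided_layers"] = tuple(enc["guided_layers"])
        config = EncoderConfig(**enc)
        rset = RelationSet(meta["entity_types"])
        model = WordPairGridModel(
            config,
            rset,
            d_g=meta["d_g"],
            d_dist=meta["d_dist"],
            d_region=meta["d_region"],
            kernel_size=meta["kernel_size"],
            dilation=meta["dilation"],
            tau=meta["tau"],
        )
        model.load_state_dict(
            {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
        )
        tokenizer = WordPieceTokenizer(meta["vocab"])
        return cls(model, tokenizer, rset)


def _batches(indices: np.ndarray, size: int):
    for i in range(0, len(indices), size):
        yield indices[i : i + size]


def train_model(
    corpus: list[LabeledSentence],
    encoder_config: EncoderConfig,
    train_config: TrainConfig,
    dev_corpus: list[LabeledSentence] | None = None,
    model: WordPairGridModel | None = None,
    tokenizer: WordPieceTokenizer | None = None,
    rset: RelationSet | None = None,
    d_g: int = 128,
    stop_at_train_f1: float | None = None,
) -> TrainedModel:
    """Train a word-pair grid model on a labeled corpus.

    Per-epoch loss components (grid, guidance, total) and, when a dev corpus
    is given, dev F1 are logged into ``history``. Fully deterministic given
    the seed. ``stop_at_train_f1`` allows early exit once the training-set F1
    reaches a target (evaluated at each epoch end when set).
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    rng = np.random.default_rng(train_config.seed)
    if tokenizer is None:
        tokenizer = WordPieceTokenizer.from_corpus(corpus)
    if rset is None:
        rset = RelationSet.from_corpus(corpus)
    encoder_config.vocab_size = max(encoder_config.vocab_size, len(tokenizer))
    if model is None:
        model = WordPairGridModel(
            encoder_config, rset, d_g=d_g, tau=train_config.tau, seed=train_config.seed
        )
    params = model.parameters()
    opt = AdamW(params, lr=train_config.lr, weight_decay=train_config.weight_decay)
    n = len(corpus)
    steps_per_epoch = math.ceil(n / train_config.batch_size)
    total_steps = steps_per_epoch * train_config.epochs
    trained = TrainedModel(model, tokenizer, rset)
    step = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(n) if train_config.shuffle else np.arange(n)
        ep_bio, ep_guid, ep_total = 0.0, 0.0, 0.0
        for idx in _batches(order, train_config.batch_size):
            batch = make_batch([corpus[i] for i in idx], tokenizer, rset)
            result = model(batch, compute_guidance=train_config.alpha > 0)
            guid = result.guidance.loss_guidance if result.guidance else None
            loss = result.loss_bioner
            if guid is not None and train_config.alpha > 0:
                loss = loss + train_config.alpha * guid
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {step}"
                )
            model.zero_grad()
            loss.backward()
            opt.step(lr_scale=linear_warmup_decay(step, total_steps,
                                                  train_config.warmup_frac))
            ep_bio += result.loss_bioner.item()
            ep_guid += guid.item() if guid is not None else 0.0
            ep_total += lval
            step += 1
        record = {
            "epoch": epoch,
            "loss_bioner": ep_bio / steps_per_epoch,
            "loss_guidance": ep_guid / steps_per_epoch,
            "loss_total": ep_total / steps_per_epoch,
        }
        if dev_corpus:
            record["dev_f1"] = evaluate_entities(
                predict(dev_corpus, trained), [s.mentions for s in dev_corpus]
            ).f1
        if stop_at_train_f1 is not None:
            record["train_f1"] = evaluate_entities(
                predict(corpus, trained), [s.mentions for s in corpus]
            ).f1
        trained.history.append(record)
        if train_config.log_every and epoch % train_config.log_every == 0:
            logger.info("epoch %d: %s", epoch, record)
        if stop_at_train_f1 is not None and record["train_f1"] >= stop_at_train_f1:
            break
    return trained


def measure_head_diversity(
    trained: TrainedModel,
    corpus: list[LabeledSentence],
    batch_size: int = 8,
    view: str = "o",
) -> float:
    """Mean off-diagonal cosine similarity of the pooled guided-head vectors,
    averaged over sentences — the head-redundancy diagnostic the guidance
    loss is meant to push down."""
    from ._autodiff import no_grad
    from .attention_guidance import assemble_head_matrices, mean_offdiagonal_cosine

    vals: list[float] = []
    for i in range(0, len(corpus), batch_size):
        batch = make_batch(corpus[i : i + batch_size], trained.tokenizer)
        with no_grad():
            result = trained.model(batch, compute_loss=False, compute_guidance=False)
        for hv in assemble_head_matrices(result.attention, tau=trained.model.tau):
            M = hv.O.data if view == "o" else hv.P.data
            vals.append(mean_offdiagonal_cosine(M))
    return float(np.mean(vals))


def predict(
    corpus: list[LabeledSentence],
    trained: TrainedModel,
    batch_size: int = 8,
) -> list[frozenset[EntityMention]]:
    """Decode argmax prediction grids for a corpus into mention sets."""
    out: list[frozenset[EntityMention]] = []
    for i in range(0, len(corpus), batch_size):
        batch = make_batch(corpus[i : i + batch_size], trained.tokenizer)
        out.extend(trained.model.predict_mentions(batch))
    return out
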