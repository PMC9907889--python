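"""Scikit-learn style estimator wrapping the word-pair grid NER model.

``GridNERTagger`` follows the sklearn estimator contract: all hyperparameters
are constructor arguments stored verbatim, ``fit`` learns from a list of
:class:`~gridner.corpus_io.LabeledSentence` (labels travel with the
sentences, so ``y`` is optional), fitted state lives in trailing-underscore
attributes, and ``get_params``/``set_params`` come from ``BaseEstimator`` so
the tagger composes with sklearn model selection.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .corpus_io import EntityMention, LabeledSentence
from .prefix_encoder import EncoderConfig
from .train_eval import TrainConfig, evaluate_entities, predict, train_model

__all__ = ["GridNERTagger"]


class GridNERTagger(BaseEstimator):
    """Word-pair relation-grid named entity tagger.

    Parameters mirror the model and optimizer knobs: encoder depth/width,
    prefix length and guided layers, the guidance weight ``alpha`` and
    temperature ``tau``, and the AdamW schedule. ``alpha=0`` disables the
    attention-guidance loss (the ablation baseline).
    """

    def __init__(
        self,
        layers: int = 2,
        heads: int = 2,
        hidden_dim: int = 32,
        prefix_length: int = 4,
        guided_layers: tuple[int, ...] | None = None,
        word_dim: int = 64,
        d_g: int = 64,
        pooling: str = "max",
        alpha: float = 0.01,
        tau: float = 2.0,
        lr: float = 1e-3,
        weight_decay: float = 0.1,
        warmup_frac: float = 0.1,
        batch_size: int = 8,
        epochs: int = 30,
        max_positions: int = 192,
        stop_at_train_f1: float | None = None,
        seed: int = 0,
    ):
        self.layers = layers
        self.heads = heads
        self.hidden_dim = hidden_dim
        self.prefix_length = prefix_length
        self.guided_layers = guided_layers
        self.word_dim = word_dim
        self.d_g = d_g
        self.pooling = pooling
        self.alpha = alpha
        self.tau = tau
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_frac = warmup_frac
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_positions = max_positions
        self.stop_at_train_f1 = stop_at_train_f1
        self.seed = seed

    # -- sklearn interface -----------------------------------------------------
    def fit(self, X: Sequence[LabeledSentence], y=None,
            dev_corpus: Sequence[LabeledSentence] | None = None) -> "GridNERTagger":
        corpus = list(X)
        encoder_config = EncoderConfig(
            layers=self.layers,
            heads=self.heads,
            hidden_dim=self.hidden_dim,
            prefix_length=self.prefix_length,
            guided_layers=self.guided_layers,
            word_dim=self.word_dim,
            pooling=self.pooling,
            max_positions=self.max_positions,
        )
        train_config = TrainConfig(
            alpha=self.alpha,
            tau=self.tau,
            batch_size=self.batch_size,
            lr=self.lr,
            weight_decay=self.weight_decay,
            warmup_frac=self.warmup_frac,
            epochs=self.epochs,
            seed=self.seed,
        )
        trained = train_model(
            corpus,
            encoder_config,
            train_config,
            dev_corpus=list(dev_corpus) if dev_corpus else None,
            d_g=self.d_g,
            stop_at_train_f1=self.stop_at_train_f1,
        )
        self.trained_ = trained
        self.model_ = trained.model
        self.tokenizer_ = trained.tokenizer
        self.relation_set_ = trained.rset
        self.history_ = trained.history
        return self

    def predict(self, X: Sequence[LabeledSentence]) -> list[frozenset[EntityMention]]:
        self._check_fitted()
        return predict(list(X), self.trained_, batch_size=self.batch_size)

    def score(self, X: Sequence[LabeledSentence], y=None) -> float:
        """Entity-level micro F1 (in percent) against the sentences' own gold
        mentions (or ``y``, a parallel list of mention iterables)."""
        self._check_fitted()
        gold: Iterable = y if y is not None else [s.mentions for s in X]
        return self.evaluate(X, gold).f1

    def evaluate(self, X: Sequence[LabeledSentence], y=None):
        self._check_fitted()
        gold = list(y) if y is not None else [s.mentions for s in X]
        return evaluate_entities(self.predict(X), gold)

    def _check_fitted(self):
        if not hasattr(self, "trained_"):
            raise RuntimeError("GridNERTagger is not fitted; call fit() first")
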