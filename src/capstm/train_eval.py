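"""Training loop, precision/recall/F evaluation and attention export.

Training uses Adam at the configured learning rate over seeded, shuffled
mini-batches.  After every epoch the model is scored on the development set
and the checkpoint with the best dev F-score (ties broken toward the
earliest epoch) is retained; training stops at ``max_epochs`` or after
``patience`` epochs without improvement.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Adam, no_grad
from .corpus_io import QuestionPair, Vocab, encode_batch, tokenize
from .model import CapsTMModel, ModelConfig, loss as bce_loss

logger = logging.getLogger("capstm")


@dataclass
class EvalMetrics:
    """Precision, recall and balanced F over the positive (match) class.

    Undefined ratios (empty denominators) are 0 by convention, as is F when
    P + R = 0.
    """

    precision: float
    recall: float
    f_score: float
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "EvalMetrics":
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return cls(precision=p, recall=r, f_score=f, tp=tp, fp=fp, fn=fn, tn=tn)

    @classmethod
    def from_predictions(cls, predicted: Sequence[int], actual: Sequence[int]) -> "EvalMetrics":
        pred = np.asarray(predicted, dtype=int)
        act = np.asarray(actual, dtype=int)
        if pred.shape != act.shape:
            raise ValueError("prediction/label length mismatch")
        tp = int(np.sum((pred == 1) & (act == 1)))
        fp = int(np.sum((pred == 1) & (act == 0)))
        fn = int(np.sum((pred == 0) & (act == 1)))
        tn = int(np.sum((pred == 0) & (act == 0)))
        return cls.from_counts(tp, fp, fn, tn)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "counts": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
        }


@dataclass
class TrainHistory:
    """Per-epoch record of one training run."""

    train_loss: list[float] = field(default_factory=list)
    dev_metrics: list[EvalMetrics] = field(default_factory=list)
    selected_epoch: int = -1
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def best_dev_f(self) -> float:
        return self.dev_metrics[self.selected_epoch].f_score


def _iter_batches(pairs: Sequence[QuestionPair], vocab: Vocab, n: int, batch_size: int,
                  order: np.ndarray | None = None):
    idx = np.arange(len(pairs)) if order is None else order
    for start in range(0, len(idx), batch_size):
        chunk = [pairs[i] for i in idx[start:start + batch_size]]
        yield encode_batch(chunk, vocab, n)


def evaluate(model: CapsTMModel, pairs: Sequence[QuestionPair]) -> EvalMetrics:
    """Score labeled pairs at the 0.5 decision threshold."""
    if not pairs:
        raise ValueError("cannot evaluate on an empty dataset")
    if any(p.label is None for p in pairs):
        raise ValueError("evaluation requires labeled pairs")
    cfg = model.config
    predicted: list[int] = []
    with no_grad():
        for batch in _iter_batches(pairs, model.vocab, cfg.max_len, cfg.batch_size):
            probs = model.forward(batch)
            predicted.extend(int(p >= 0.5) for p in probs.data)
    return EvalMetrics.from_predictions(predicted, [p.label for p in pairs])


def train(
    model: CapsTMModel,
    train_pairs: Sequence[QuestionPair],
    dev_pairs: Sequence[QuestionPair],
    max_epochs: int = 50,
    patience: int = 5,
    seed: int = 0,
) -> tuple[CapsTMModel, TrainHistory]:
    """Fit the model; returns the best-dev-F parameters and the history.

    ``patience=0`` trains for exactly one epoch.  The run is deterministic
    for a fixed seed: batch shuffling and dropout masks both derive from it.
    """
    if not train_pairs or not dev_pairs:
        raise ValueError("train and dev splits must be non-empty")
    cfg = model.config
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(seed)
    dropout_rng = np.random.default_rng(seed + 1)
    history = TrainHistory(seed=seed, config=cfg.to_dict())
    best_state: dict[str, np.ndarray] | None = None
    best_f = -1.0
    epochs_since_best = 0

    for epoch in range(max_epochs):
        order = shuffle_rng.permutation(len(train_pairs))
        epoch_losses = []
        for batch in _iter_batches(train_pairs, model.vocab, cfg.max_len, cfg.batch_size, order):
            probs = model.forward(batch, training=True, dropout_rng=dropout_rng)
            batch_loss = bce_loss(probs, batch.labels)
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
            epoch_losses.append(batch_loss.item())
        history.train_loss.append(float(np.mean(epoch_losses)))
        metrics = evaluate(model, dev_pairs)
        history.dev_metrics.append(metrics)
        logger.info(
            "epoch %d: loss=%.4f dev P=%.4f R=%.4f F=%.4f",
            epoch, history.train_loss[-1], metrics.precision, metrics.recall, metrics.f_score,
        )
        if metrics.f_score > best_f:
            best_f = metrics.f_score
            history.selected_epoch = epoch
            best_state = {k: t.data.copy() for k, t in model.named_parameters().items()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if patience == 0 or epochs_since_best >= patience:
            break

    assert best_state is not None
    for name, tensor in model.named_parameters().items():
        tensor.data = best_state[name]
    return model, history


def export_attention(model: CapsTMModel, pair: QuestionPair, out_path) -> np.ndarray:
    """Write the pair's attention weight matrix as a token-labeled TSV.

    Rows are the tokens of ``text_a``, columns the tokens of ``text_b``;
    cell (k, s) is the normalized weight of token s when attending for
    token k.  In softmax mode every row sums to 1.  Models trained without
    attention cannot export one.
    """
    if not model.config.use_attention:
        raise ValueError(
            "this model was built with use_attention=false (attention-free "
            "ablation); it has no attention matrix to export"
        )
    batch = encode_batch([pair], model.vocab, model.config.max_len)
    prediction = model.predict(batch, return_attention=True)[0]
    weights = prediction.attention
    toks_a = tokenize(pair.text_a)[: model.config.max_len]
    toks_b = tokenize(pair.text_b)[: model.config.max_len]
    out_path = Path(out_path)
    with out_path.open("w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(toks_b) + "\n")
        for tok, row in zip(toks_a, weights):
            fh.write(tok + "\t" + "\t".join(f"{w:.6f}" for w in row) + "\n")
    return weights
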