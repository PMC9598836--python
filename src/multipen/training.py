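"""Training loop: survival-ranking objective, seeded mini-batching, Adam.

The objective is a pairwise hinge ranking loss on uncensored pairs: for
every ordered pair (i, j) with time_i < time_j the model is penalised
max(0, margin + s_i - s_j), i.e. the shorter-lived sample must score at
least `margin` below the longer-lived one.  The loss is computed within
each mini-batch, applied to the ensemble-mean score and, with equal
weight, to each sub-model's own score — the sub-models stay individually
informative while training jointly through the shared attention layers.
Pairs with exactly equal survival times carry no order information and
are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .autodiff import Adam, Tensor
from .config import ModelConfig
from .model import MultiPENModel

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "ranking_loss",
    "make_minibatches",
    "train",
]


@dataclass
class TrainingHistory:
    """Per-batch loss trace plus provenance."""

    losses: list[float] = field(default_factory=list)  # epoch-major order
    epochs: int = 0
    minibatches_per_epoch: int = 0
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.losses)

    def epoch_means(self) -> np.ndarray:
        k = self.minibatches_per_epoch
        return np.asarray(self.losses).reshape(self.epochs, k).mean(axis=1)


def _comparable_mask(time: np.ndarray) -> np.ndarray:
    """mask[i, j] = 1 where time_i < time_j (strict; ties carry no order)."""
    return (time[:, None] < time[None, :]).astype(np.float64)


def ranking_loss(pred: np.ndarray, time: np.ndarray, margin: float = 0.1) -> float:
    """Mean hinge over all ordered pairs (i, j) with time_i < time_j.

    Returns 0 when no comparable pairs exist (all times tied).
    """
    pred = np.asarray(pred, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    if pred.shape != time.shape or pred.ndim != 1:
        raise ValueError("pred and time must be 1-D vectors of equal length")
    if pred.size < 2:
        raise ValueError("ranking loss needs at least 2 samples")
    mask = _comparable_mask(time)
    n_pairs = mask.sum()
    if n_pairs == 0:
        return 0.0
    hinge = np.maximum(0.0, margin + pred[:, None] - pred[None, :])
    return float((hinge * mask).sum() / n_pairs)


def _ranking_loss_rows(preds: Tensor, time: np.ndarray, margin: float) -> Tensor:
    """Differentiable row-wise ranking loss.

    preds: (m, batch) — each row is one scoring of the batch.  Returns a
    scalar Tensor: the mean over rows of each row's mean pairwise hinge.
    """
    m, b = preds.shape
    mask = _comparable_mask(time)
    n_pairs = mask.sum()
    if n_pairs == 0:
        return Tensor(0.0)
    diff = preds.reshape(m, b, 1) - preds.reshape(m, 1, b)
    hinge = (diff + margin).relu() * Tensor(mask)
    return hinge.sum(axis=(1, 2)).mean() / n_pairs


def training_loss(preds: Tensor, time: np.ndarray, margin: float) -> Tensor:
    """Ensemble-mean ranking loss plus the average per-sub-model ranking loss."""
    n, b = preds.shape
    ens = preds.mean(axis=0).reshape(1, b)
    return _ranking_loss_rows(ens, time, margin) + _ranking_loss_rows(preds, time, margin)


def make_minibatches(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Randomly partition indices 0..n-1 into k batches of near-equal size."""
    if k < 1:
        raise ValueError("number of mini-batches must be >= 1")
    if k > n:
        raise ValueError(f"cannot form {k} mini-batches from {n} samples")
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def train(
    model: MultiPENModel,
    data: Mapping[str, np.ndarray],
    time: np.ndarray,
    config: ModelConfig,
) -> tuple[MultiPENModel, TrainingHistory]:
    """Train in place with Adam on the pairwise ranking objective.

    `data` maps modality -> (samples, features) arrays in a shared
    sample order; `time` holds the observed survival times (all samples
    uncensored).  Runs epochs x minibatches_per_epoch gradient steps;
    the model is returned in eval mode.  Deterministic for a fixed
    (config.seed, data) pair.
    """
    time = np.asarray(time, dtype=np.float64)
    n = time.size
    k = config.minibatches_per_epoch
    if n < 2 * k:
        raise ValueError(f"{n} samples cannot fill {k} mini-batches with >= 2 samples each")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    params = model.parameters()
    opt = Adam(params, config.learning_rate, config.adam_beta1, config.adam_beta2, config.adam_eps)
    history = TrainingHistory(epochs=config.epochs, minibatches_per_epoch=k, seed=config.seed)
    modalities = [m for m in model.fusion_order if model.attention_layer(m) is not None]
    step = 0
    for _ in range(config.epochs):
        for idx in make_minibatches(n, k, rng):
            batch = {m: data[m][idx] for m in modalities}
            # the hinge trains on raw (pre-tanh) scores: same ordering as the
            # bounded output, but no saturation plateau for the gradient
            preds = model.forward(batch, training=True, rng=rng, squash=False)
            loss = training_loss(preds, time[idx], config.ranking_margin)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite loss at training step {step}")
            if loss.requires_grad:
                opt.zero_grad()
                loss.backward()
                opt.step()
            history.losses.append(value)
            step += 1
    return model, history
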