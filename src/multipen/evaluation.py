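"""Concordance-index evaluation and repeated K-fold cross-validation.

The protocol mirrors the modeled cohort study: 125 uncensored samples,
five-fold cross-validation repeated 20 times (100 experiments), with
every preprocessing statistic fitted on the training partition of each
split only, so held-out samples never leak into gene filtering or
clinical encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .config import ModelConfig
from .data_io import (
    ClinicalTable,
    ExpressionMatrix,
    SurvivalLabels,
    fit_preprocessor,
    transform_cohort,
)
from .model import ensemble_predict, init_model
from .training import train

__all__ = [
    "FoldSplit",
    "ExperimentResult",
    "concordance_index",
    "make_cv_splits",
    "run_experiment",
    "derive_split_seed",
]


def concordance_index(pred: np.ndarray, time: np.ndarray) -> float:
    """Concordance between predicted scores and observed survival times.

    Over all sample pairs with strictly different times, a pair is
    concordant when the higher score belongs to the longer-lived sample
    (scores are likelihood-of-survival, not hazard).  Concordant pairs
    score 1, tied predictions 0.5, discordant 0; the result is the mean
    over comparable pairs.  Raises when no pair of times differs.
    """
    pred = np.asarray(pred, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    if pred.shape != time.shape or pred.ndim != 1:
        raise ValueError("pred and time must be 1-D vectors of equal length")
    if pred.size < 2:
        raise ValueError("concordance index needs at least 2 samples")
    comparable = time[:, None] < time[None, :]  # ordered pairs, strict
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs: all survival times are equal")
    dpred = pred[None, :] - pred[:, None]  # score_j - score_i for pair (i, j)
    score = np.where(dpred > 0, 1.0, np.where(dpred == 0, 0.5, 0.0))
    return float((score * comparable).sum() / n_pairs)


@dataclass
class FoldSplit:
    """One train/test division of the cohort (1-based repeat and fold)."""

    repeat: int
    fold: int
    train_ids: list[str]
    test_ids: list[str]


def make_cv_splits(
    sample_ids: Sequence[str], k: int, repeats: int, seed: int
) -> list[FoldSplit]:
    """Repeated K-fold splits: per repeat a fresh random near-equal partition."""
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    splits: list[FoldSplit] = []
    for r in range(1, repeats + 1):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for f, test_idx in enumerate(folds, start=1):
            test_set = set(test_idx.tolist())
            train_ids = [sample_ids[i] for i in perm if i not in test_set]
            test_ids = [sample_ids[i] for i in test_idx]
            splits.append(FoldSplit(r, f, train_ids, test_ids))
    return splits


def derive_split_seed(seed: int, repeat: int, fold: int) -> int:
    """Deterministic per-split model seed, independent across splits."""
    ss = np.random.SeedSequence([int(seed), int(repeat), int(fold)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentResult:
    """All split-level C-indices of one repeated-CV experiment."""

    cindices: np.ndarray
    splits: list[dict]
    seed: int
    k: int
    repeats: int
    config: ModelConfig | None = None
    attention: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.cindices))

    @property
    def sd(self) -> float:
        return float(np.std(self.cindices, ddof=1))

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "k": self.k,
            "repeats": self.repeats,
            "mean_cindex": self.mean,
            "sd_cindex": self.sd,
            "splits": self.splits,
            "config": None if self.config is None else self.config.to_dict(),
        }
        return json.dumps(payload, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


PredictFn = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def run_experiment(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    clinical: ClinicalTable | None,
    survival: SurvivalLabels,
    config: ModelConfig,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    predict_fn: PredictFn | None = None,
    collect_attention: bool = False,
) -> ExperimentResult:
    """Repeated K-fold evaluation with leakage-free preprocessing.

    For every split: fit the Preprocessor on the training partition only,
    transform both partitions, train a freshly initialized model (seed
    derived from (seed, repeat, fold)), score the held-out samples and
    record the C-index.  Only uncensored samples enter the protocol.

    ``predict_fn(X_train, t_train, X_test) -> scores`` lets an external
    learner (e.g. ridge or Coxnet) run under the identical split and
    preprocessing protocol instead of the network; it receives the fused
    sample-major feature matrices.

    ``collect_attention`` additionally records each split model's mean
    attention per feature (for cross-validated attention aggregation).
    """
    survival = survival.uncensored()
    splits = make_cv_splits(survival.sample_ids, k, repeats, seed)
    cindices: list[float] = []
    split_meta: list[dict] = []
    attention: list[dict] = []
    for sp in splits:
        if len(sp.test_ids) < 2:
            raise ValueError(f"split repeat={sp.repeat} fold={sp.fold} has < 2 test samples")
        train_clin = clinical.subset(sp.train_ids) if clinical is not None else None
        prep = fit_preprocessor(
            mrna.subset_samples(sp.train_ids),
            mirna.subset_samples(sp.train_ids),
            train_clin,
            log_base=config.log_base,
        )
        tr = transform_cohort(prep, mrna, mirna, clinical, sp.train_ids)
        te = transform_cohort(prep, mrna, mirna, clinical, sp.test_ids)
        t_train = survival.subset(sp.train_ids).time
        t_test = survival.subset(sp.test_ids).time
        split_seed = derive_split_seed(seed, sp.repeat, sp.fold)
        if predict_fn is not None:
            X_tr = np.hstack([tr["mrna"], tr["mirna"], tr["clinical"]])
            X_te = np.hstack([te["mrna"], te["mirna"], te["clinical"]])
            scores = np.asarray(predict_fn(X_tr, t_train, X_te), dtype=np.float64)
        else:
            p_c = tr["clinical"].shape[1]
            split_config = ModelConfig.from_dict({**config.to_dict(), "seed": split_seed})
            model = init_model(
                split_config,
                tr["mrna"].shape[1],
                tr["mirna"].shape[1],
                p_c,
                seed=split_seed,
            )
            model, _ = train(model, tr, t_train, split_config)
            # rank on raw scores: same ordering as the tanh output, but no
            # float ties at the saturation plateaus
            scores, _ = ensemble_predict(model, te, squash=False)
            if collect_attention:
                att: dict = {"repeat": sp.repeat, "fold": sp.fold}
                for modality in ("mrna", "mirna", "clinical"):
                    layer = model.attention_layer(modality)
                    if layer is None:
                        continue
                    a = layer.attention(tr[modality]).mean(axis=0)
                    att[modality] = {"feature_ids": tr["feature_ids"][modality], "mean_attention": a.tolist()}
                attention.append(att)
        ci = concordance_index(scores, t_test)
        cindices.append(ci)
        split_meta.append(
            {
                "repeat": sp.repeat,
                "fold": sp.fold,
                "n_train": len(sp.train_ids),
                "n_test": len(sp.test_ids),
                "model_seed": split_seed,
                "cindex": ci,
            }
        )
    return ExperimentResult(
        np.asarray(cindices), split_meta, seed, k, repeats, config, attention
    )
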