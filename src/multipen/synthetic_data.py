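"""Synthetic multi-omics survival cohorts with known prognostic structure.

The generator emulates the shape of the modeled cohort — 125 uncensored
samples with log-scale mRNA and miRNA expression, zero-inflation,
clinical covariates — while planting a known prognostic signal so that
every pipeline stage (preprocessing, training, evaluation, attention
recovery) can be validated against ground truth.

Generative model
----------------
A latent prognostic factor u ~ N(0, 1) per sample drives the planted
features.  Planted mRNAs have log2 expression mu_g + u + noise_sd * eps;
each planted miRNA is negatively coupled (correlation -rho) to one
planted target mRNA, encoding the motivating biology that miRNAs repress
their target mRNAs — so the miRNA layer carries complementary signal and
multi-omics fusion is advantageous by construction.  Null genes are pure
noise around gene-specific baselines.  Raw expression is 2**log2-value,
then zero-inflated at rate pi and masked missing at the missing rate.

The latent risk is
    risk = beta * (z(mean planted mRNA) - z(mean planted miRNA)) + clinical effects,
and survival time follows a proportional-hazards Weibull,
    T = scale * (E / exp(risk))**(1/shape),  E ~ Exponential(1),
(shape 1 = exponential; the shape only rescales times, it does not change
pairwise orderings, so the true concordance is set by the risk spread).
All events are observed (uncensored cohort).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import (
    ClinicalTable,
    ExpressionMatrix,
    SurvivalLabels,
    read_clinical_table,
    read_expression_matrix,
    read_survival_labels,
    write_clinical_table,
    write_expression_matrix,
    write_survival_labels,
)

__all__ = ["CohortSpec", "CohortTruth", "Cohort", "generate_cohort", "write_cohort", "read_cohort"]


_CATEGORIES = {
    "sex": ["male", "female"],
    "race": ["white", "black", "asian", "other"],
    "ethnicity": ["non-hispanic", "hispanic"],
    "tumor_grade": ["G2", "G3"],
    "idh_codel_subtype": ["IDHmut-codel", "IDHmut-non-codel", "IDHwt"],
    "codeletion_1p19q": ["codel", "non-codel"],
}

_CATEGORY_PROBS = {
    "sex": [0.55, 0.45],
    "race": [0.75, 0.1, 0.1, 0.05],
    "ethnicity": [0.85, 0.15],
    "tumor_grade": [0.5, 0.5],
    "idh_codel_subtype": [0.3, 0.45, 0.25],
    "codeletion_1p19q": [0.3, 0.7],
}


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort."""

    n_samples: int = 125
    p_mrna: int = 1000
    p_mirna: int = 200
    n_prognostic_mrna: int = 20
    n_prognostic_mirna: int = 10
    effect_size: float = 1.0  # beta: log-hazard scale of the omics signal
    coupling: float = 0.6  # rho: |correlation| of planted miRNA with its target mRNA
    zero_inflation: float = 0.05  # pi: probability a raw expression value is zeroed
    missing_rate: float = 0.0
    noise_sd: float = 1.0  # gene-level log2 noise around the baseline
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: {
            "tumor_grade=G3": 0.4,
            "idh_codel_subtype=IDHwt": 0.6,
            "age_at_diagnosis": 0.3,
        }
    )
    survival_scale_days: float = 1000.0
    weibull_shape: float = 1.0
    n_high_zero_mrna: int = 0  # extra null mRNAs given an elevated zero rate
    high_zero_rate: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_prognostic_mrna > self.p_mrna or self.n_prognostic_mirna > self.p_mirna:
            raise ValueError("prognostic gene count exceeds total gene count")
        if self.n_prognostic_mrna < 0 or self.n_prognostic_mirna < 0:
            raise ValueError("prognostic gene counts must be non-negative")
        if not 0.0 <= self.zero_inflation < 1.0 or not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("zero_inflation and missing_rate must lie in [0, 1)")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_high_zero_mrna + self.n_prognostic_mrna > self.p_mrna:
            raise ValueError("high-zero gene count exceeds available null mRNAs")

    # -- presets -------------------------------------------------------
    @classmethod
    def default(cls, seed: int = 0) -> "CohortSpec":
        return cls(seed=seed)

    @classmethod
    def null_cohort(cls, seed: int = 0) -> "CohortSpec":
        """No planted signal anywhere: survival is independent of all features."""
        return cls(
            p_mrna=500,
            p_mirna=100,
            effect_size=0.0,
            clinical_effects={},
            seed=seed,
        )

    @classmethod
    def strong_signal(cls, seed: int = 0) -> "CohortSpec":
        """A cohort whose planted signal dominates the survival ordering.

        20 prognostic mRNAs among 500 and 10 miRNAs among 100, low gene
        noise, a large effect size and no zero-inflation, so the true
        risk score is almost perfectly concordant with survival and the
        signal is recoverable from 100 training samples.
        """
        return cls(
            p_mrna=500,
            p_mirna=100,
            effect_size=8.0,
            coupling=0.8,
            noise_sd=0.2,
            zero_inflation=0.0,
            clinical_effects={
                "tumor_grade=G3": 0.4,
                "idh_codel_subtype=IDHwt": 0.6,
                "age_at_diagnosis": 0.3,
            },
            seed=seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    prognostic_mrna: list[str]
    prognostic_mirna: list[str]
    risk: np.ndarray  # latent per-sample log-hazard
    high_zero_mrna: list[str]
    spec: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "prognostic_mrna": self.prognostic_mrna,
                "prognostic_mirna": self.prognostic_mirna,
                "risk": np.asarray(self.risk).tolist(),
                "high_zero_mrna": self.high_zero_mrna,
                "spec": self.spec,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        return cls(
            d["prognostic_mrna"],
            d["prognostic_mirna"],
            np.asarray(d["risk"], dtype=np.float64),
            d.get("high_zero_mrna", []),
            d["spec"],
        )


@dataclass
class Cohort:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    clinical: ClinicalTable
    survival: SurvivalLabels
    truth: CohortTruth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort from the generative model (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    mrna_ids = [f"GENE{i:04d}" for i in range(spec.p_mrna)]
    mirna_ids = [f"hsa-mir-{i:04d}" for i in range(spec.p_mirna)]

    u = rng.normal(size=n)  # latent prognostic factor

    # mRNA layer: gene baselines + noise; planted genes load on u
    mu_m = rng.uniform(3.0, 9.0, size=spec.p_mrna)
    log_mrna = mu_m[:, None] + spec.noise_sd * rng.normal(size=(spec.p_mrna, n))
    planted_m = np.sort(rng.choice(spec.p_mrna, size=spec.n_prognostic_mrna, replace=False))
    log_mrna[planted_m, :] += u[None, :]

    # miRNA layer: planted miRNAs anti-correlated with a planted target mRNA
    mu_mi = rng.uniform(3.0, 9.0, size=spec.p_mirna)
    log_mirna = mu_mi[:, None] + spec.noise_sd * rng.normal(size=(spec.p_mirna, n))
    planted_mi = np.sort(rng.choice(spec.p_mirna, size=spec.n_prognostic_mirna, replace=False))
    rho = spec.coupling
    for j, mi in enumerate(planted_mi):
        if spec.n_prognostic_mrna == 0:
            break
        target = planted_m[j % spec.n_prognostic_mrna]
        z_target = _zscore(log_mrna[target, :])
        eta = rng.normal(size=n)
        log_mirna[mi, :] = mu_mi[mi] + spec.noise_sd * (
            -rho * z_target + np.sqrt(max(0.0, 1.0 - rho * rho)) * eta
        )

    # latent risk and survival (proportional hazards, all events observed)
    risk = np.zeros(n)
    if spec.effect_size != 0.0 and spec.n_prognostic_mrna > 0:
        sig_m = _zscore(log_mrna[planted_m, :].mean(axis=0))
        sig_mi = (
            _zscore(log_mirna[planted_mi, :].mean(axis=0))
            if spec.n_prognostic_mirna > 0
            else 0.0
        )
        risk = risk + spec.effect_size * (sig_m - sig_mi)

    # clinical covariates
    categorical: dict[str, list[str | None]] = {}
    for name, cats in _CATEGORIES.items():
        draws = rng.choice(len(cats), size=n, p=_CATEGORY_PROBS[name])
        categorical[name] = [cats[i] for i in draws]
    age = np.clip(rng.normal(47.0, 12.0, size=n), 18.0, 89.0)
    mutations = rng.poisson(30.0, size=n).astype(np.float64)
    numeric = {"age_at_diagnosis": age, "mutation_count": mutations}

    for key, effect in spec.clinical_effects.items():
        if "=" in key:
            var, cat = key.split("=", 1)
            labels = categorical[var]
            risk = risk + effect * np.asarray([1.0 if l == cat else 0.0 for l in labels])
        else:
            risk = risk + effect * _zscore(numeric[key])

    # higher risk = shorter survival; Weibull proportional hazards
    base = rng.exponential(1.0, size=n)
    time = spec.survival_scale_days * (base * np.exp(-risk)) ** (1.0 / spec.weibull_shape)
    time = np.maximum(time, 1e-3)
    event = np.ones(n, dtype=np.int64)

    # raw scale, zero-inflation, elevated-zero subset, missingness
    raw_m = np.power(2.0, log_mrna)
    raw_mi = np.power(2.0, log_mirna)
    if spec.zero_inflation > 0:
        raw_m[rng.random(raw_m.shape) < spec.zero_inflation] = 0.0
        raw_mi[rng.random(raw_mi.shape) < spec.zero_inflation] = 0.0
    high_zero_idx = np.asarray([], dtype=np.int64)
    if spec.n_high_zero_mrna > 0:
        null_pool = np.setdiff1d(np.arange(spec.p_mrna), planted_m)
        high_zero_idx = np.sort(rng.choice(null_pool, size=spec.n_high_zero_mrna, replace=False))
        mask = rng.random((spec.n_high_zero_mrna, n)) < spec.high_zero_rate
        rows = raw_m[high_zero_idx, :]
        rows[mask] = 0.0
        raw_m[high_zero_idx, :] = rows
    if spec.missing_rate > 0:
        raw_m[rng.random(raw_m.shape) < spec.missing_rate] = np.nan
        raw_mi[rng.random(raw_mi.shape) < spec.missing_rate] = np.nan

    truth = CohortTruth(
        prognostic_mrna=[mrna_ids[i] for i in planted_m],
        prognostic_mirna=[mirna_ids[i] for i in planted_mi],
        risk=risk,
        high_zero_mrna=[mrna_ids[i] for i in high_zero_idx],
        spec=spec.to_dict(),
    )
    return Cohort(
        mrna=ExpressionMatrix(mrna_ids, sample_ids, raw_m),
        mirna=ExpressionMatrix(mirna_ids, sample_ids, raw_mi),
        clinical=ClinicalTable(sample_ids, categorical, numeric),
        survival=SurvivalLabels(sample_ids, time, event),
        truth=truth,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as the TSV dialect consumed by data_io plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": out / "mrna.tsv",
        "mirna": out / "mirna.tsv",
        "clinical": out / "clinical.tsv",
        "survival": out / "survival.tsv",
        "truth": out / "truth.json",
    }
    write_expression_matrix(cohort.mrna, paths["mrna"])
    write_expression_matrix(cohort.mirna, paths["mirna"])
    write_clinical_table(cohort.clinical, paths["clinical"])
    write_survival_labels(cohort.survival, paths["survival"])
    paths["truth"].write_text(cohort.truth.to_json(), encoding="utf-8")
    return paths


def read_cohort(in_dir: str | Path) -> Cohort:
    d = Path(in_dir)
    truth_path = d / "truth.json"
    truth = (
        CohortTruth.from_json(truth_path.read_text(encoding="utf-8"))
        if truth_path.exists()
        else CohortTruth([], [], np.asarray([]), [], {})
    )
    return Cohort(
        mrna=read_expression_matrix(d / "mrna.tsv"),
        mirna=read_expression_matrix(d / "mirna.tsv"),
        clinical=read_clinical_table(d / "clinical.tsv"),
        survival=read_survival_labels(d / "survival.tsv"),
        truth=truth,
    )
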