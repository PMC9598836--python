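"""Attention-based ranking of prognostic features.

The attention gate of each data type assigns every feature a value in
(0, 1) per sample; averaging over the cohort gives a single importance
score per gene, and sorting (descending, ties broken by feature ID)
yields the prognostic ranking.  The per-sample matrix can be kept for
alternative scalarizations (median, max, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import MultiPENModel

__all__ = [
    "AttentionReport",
    "compute_gene_attention",
    "rank_genes",
    "permutation_enrichment_pvalue",
    "aggregate_attention",
    "plot_top_genes",
]


def _ranks_for(feature_ids: Sequence[str], mean_attention: np.ndarray) -> np.ndarray:
    """Rank 1 = highest mean attention; ties broken by feature-ID order."""
    order = sorted(range(len(feature_ids)), key=lambda i: (-mean_attention[i], feature_ids[i]))
    ranks = np.empty(len(feature_ids), dtype=np.int64)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


@dataclass
class AttentionReport:
    """Per-feature mean attention and rank for one data type."""

    datatype: str  # "mrna" | "mirna" | "clinical"
    feature_ids: list[str]
    mean_attention: np.ndarray  # (p,), values in (0, 1)
    ranks: np.ndarray  # permutation of 1..p
    attention_matrix: np.ndarray | None = None  # (samples, p), optional

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mean_attention": self.mean_attention,
                "rank": self.ranks,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_gene_attention(
    model: MultiPENModel,
    data: Mapping[str, np.ndarray],
    feature_ids: Mapping[str, Sequence[str]],
    keep_matrix: bool = False,
) -> list[AttentionReport]:
    """Per-datatype attention reports for a trained model.

    ``data`` holds sample-major matrices preprocessed with the model's
    own Preprocessor; attention is evaluated per sample and averaged
    over the cohort (the mean is invariant to sample order).
    """
    reports: list[AttentionReport] = []
    for modality in model.fusion_order:
        layer = model.attention_layer(modality)
        if layer is None:
            continue
        ids = list(feature_ids[modality])
        x = np.asarray(data[modality], dtype=np.float64)
        if x.shape[1] != layer.p or len(ids) != layer.p:
            raise ValueError(
                f"{modality}: model expects {layer.p} features, got matrix with "
                f"{x.shape[1]} and {len(ids)} feature IDs"
            )
        a = layer.attention(x)  # (samples, p)
        mean_att = a.mean(axis=0)
        reports.append(
            AttentionReport(
                datatype=modality,
                feature_ids=ids,
                mean_attention=mean_att,
                ranks=_ranks_for(ids, mean_att),
                attention_matrix=a if keep_matrix else None,
            )
        )
    return reports


def rank_genes(report: AttentionReport, top_k: int) -> pd.DataFrame:
    """Top-k features by rank (deterministic under ties)."""
    if top_k < 0:
        raise ValueError("top_k must be non-negative")
    if top_k > report.p:
        warnings.warn(
            f"top_k={top_k} exceeds the {report.p} available features; clamping",
            stacklevel=2,
        )
        top_k = report.p
    return report.to_frame().head(top_k).reset_index(drop=True)


def permutation_enrichment_pvalue(
    report: AttentionReport,
    planted_ids: Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation test: do planted features carry higher attention?

    Statistic: mean attention of the planted set minus mean attention of
    the remaining features.  The label sets are permuted
    ``n_permutations`` times; returns (observed statistic, p-value) with
    the add-one correction p = (1 + #{perm >= obs}) / (1 + n).
    """
    planted = set(planted_ids)
    is_planted = np.asarray([f in planted for f in report.feature_ids])
    n_planted = int(is_planted.sum())
    if n_planted == 0 or n_planted == report.p:
        raise ValueError("planted set must be a non-empty proper subset of the features")
    att = report.mean_attention
    observed = float(att[is_planted].mean() - att[~is_planted].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(report.p)
        sel = perm[:n_planted]
        rest = perm[n_planted:]
        if att[sel].mean() - att[rest].mean() >= observed:
            count += 1
    pvalue = (1 + count) / (1 + n_permutations)
    return observed, float(pvalue)


def aggregate_attention(split_records: Sequence[Mapping]) -> list[AttentionReport]:
    """Average per-gene attention over the trained models of many CV splits.

    ``split_records`` is the ``attention`` list of an ExperimentResult.
    Features are matched by ID; a gene filtered out of some splits is
    averaged over the splits that kept it.
    """
    reports: list[AttentionReport] = []
    for modality in ("mrna", "mirna", "clinical"):
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for rec in split_records:
            if modality not in rec:
                continue
            for fid, val in zip(rec[modality]["feature_ids"], rec[modality]["mean_attention"]):
                sums[fid] = sums.get(fid, 0.0) + float(val)
                counts[fid] = counts.get(fid, 0) + 1
        if not sums:
            continue
        ids = sorted(sums)
        mean_att = np.asarray([sums[f] / counts[f] for f in ids])
        reports.append(
            AttentionReport(modality, ids, mean_att, _ranks_for(ids, mean_att))
        )
    return reports


def plot_top_genes(report: AttentionReport, top_k: int, path: str | Path) -> None:
    """Horizontal bar plot of the top-k features by mean attention."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = rank_genes(report, top_k)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(table))))
    ax.barh(table["feature_id"][::-1], table["mean_attention"][::-1], color="#4878a8")
    ax.set_xlabel("mean attention")
    ax.set_title(f"top {len(table)} {report.datatype} features")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
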