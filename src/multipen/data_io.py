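"""Reading, preprocessing and writing of expression, clinical and survival data.

Preprocessing follows a strict fit-on-training-only contract: every
statistic that downstream transforms depend on (surviving gene lists,
category vocabularies, numeric means and standard deviations) is fitted
on the training partition and applied verbatim to held-out data, so a
held-out sample can never influence its own preprocessing.

Expression files are plain text (TSV or CSV): first row sample IDs,
first column gene IDs, "." decimal, empty cell = missing value.  Missing
entries are preserved as NaN markers, never coerced to zero — genes with
any missing value are excluded later, mirroring the cohort's rule of
dropping rather than imputing.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "FeatureMatrix",
    "Preprocessor",
    "SurvivalLabels",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_survival_labels",
    "write_survival_labels",
    "filter_genes",
    "log_normalize",
    "fit_clinical_encoder",
    "encode_clinical",
    "fit_preprocessor",
    "transform_cohort",
    "LOG_BASES",
]

#: supported log bases for expression normalisation, value = log(base)
LOG_BASES = {"log2": math.log(2.0), "ln": 1.0, "log10": math.log(10.0)}

#: default numeric clinical variables; everything else is categorical
DEFAULT_NUMERIC_VARS = ("age_at_diagnosis", "mutation_count")

UNKNOWN = "unknown"


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one omics layer.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``; missing entries are NaN.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not present in matrix") from None
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present in matrix") from None
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows, :])


@dataclass
class ClinicalTable:
    """Per-sample clinical records: categorical labels and numeric values.

    Categorical missing markers are ``None``; numeric missing markers NaN.
    """

    sample_ids: list[str]
    categorical: dict[str, list[str | None]] = field(default_factory=dict)
    numeric: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name, labels in self.categorical.items():
            if len(labels) != n:
                raise ValueError(f"categorical variable {name!r} has {len(labels)} values for {n} samples")
        for name in list(self.numeric):
            arr = np.asarray(self.numeric[name], dtype=np.float64)
            if arr.shape != (n,):
                raise ValueError(f"numeric variable {name!r} has shape {arr.shape} for {n} samples")
            self.numeric[name] = arr

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not present in clinical table") from None
        return ClinicalTable(
            list(sample_ids),
            {k: [v[r] for r in rows] for k, v in self.categorical.items()},
            {k: v[rows] for k, v in self.numeric.items()},
        )


@dataclass
class FeatureMatrix:
    """Encoded clinical features (features x samples)."""

    feature_names: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.feature_names), len(self.sample_ids)):
            raise ValueError("feature matrix shape mismatch")


@dataclass
class SurvivalLabels:
    """Observed survival time (days) and event indicator per sample."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("survival arrays must have one entry per sample")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalLabels":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not present in survival labels") from None
        return SurvivalLabels(list(sample_ids), self.time[rows], self.event[rows])

    def uncensored(self) -> "SurvivalLabels":
        keep = [s for s, e in zip(self.sample_ids, self.event) if e == 1]
        return self.subset(keep)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MISSING_STRINGS = {"", "na", "nan", "null", "none"}


def _parse_cell(text: str, path, line_no: int) -> float:
    if text.strip().lower() in _MISSING_STRINGS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"{path}: line {line_no}: cannot parse {text!r} as a number") from None


def _read_table(path: str | Path, delimiter: str | None) -> list[list[str]]:
    delimiter = _infer_delimiter(path, delimiter)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter)]
    if not rows:
        raise ValueError(f"{path}: file is empty")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row at line {i + 1}: expected {width} fields, got {len(row)}"
            )
    return rows


def read_expression_matrix(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    First row holds sample IDs (first cell is a corner label), first
    column gene IDs.  Empty cells are recorded as missing (NaN), not 0.
    Duplicate IDs or ragged rows raise ``ValueError``.
    """
    rows = _read_table(path, delimiter)
    sample_ids = rows[0][1:]
    gene_ids = [row[0] for row in rows[1:]]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = np.empty((len(gene_ids), len(sample_ids)), dtype=np.float64)
    for i, row in enumerate(rows[1:], start=2):
        values[i - 2, :] = [_parse_cell(c, path, i) for c in row[1:]]
    return ExpressionMatrix(gene_ids, sample_ids, values)


def _fmt(v: float) -> str:
    return "" if np.isnan(v) else format(v, ".17g")


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    delimiter = _infer_delimiter(path, delimiter)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["gene_id", *m.sample_ids])
        for gid, row in zip(m.gene_ids, m.values):
            w.writerow([gid, *[_fmt(v) for v in row]])


def read_clinical_table(
    path: str | Path,
    numeric_vars: Sequence[str] = DEFAULT_NUMERIC_VARS,
    delimiter: str | None = None,
) -> ClinicalTable:
    """Read a clinical table (samples in rows, header row of variable names)."""
    rows = _read_table(path, delimiter)
    header = rows[0]
    if len(header) < 2:
        raise ValueError(f"{path}: clinical table needs a sample_id column plus variables")
    var_names = header[1:]
    sample_ids = [row[0] for row in rows[1:]]
    categorical: dict[str, list[str | None]] = {}
    numeric: dict[str, list[float]] = {}
    for j, name in enumerate(var_names, start=1):
        col = [row[j] for row in rows[1:]]
        if name in numeric_vars:
            numeric[name] = [
                _parse_cell(c, path, i + 2) for i, c in enumerate(col)
            ]
        else:
            categorical[name] = [None if c.strip().lower() in _MISSING_STRINGS else c for c in col]
    return ClinicalTable(sample_ids, categorical, {k: np.asarray(v) for k, v in numeric.items()})


def write_clinical_table(t: ClinicalTable, path: str | Path, delimiter: str | None = None) -> None:
    delimiter = _infer_delimiter(path, delimiter)
    names = list(t.categorical) + list(t.numeric)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["sample_id", *names])
        for j, sid in enumerate(t.sample_ids):
            row: list[str] = [sid]
            for name in t.categorical:
                v = t.categorical[name][j]
                row.append("" if v is None else v)
            for name in t.numeric:
                row.append(_fmt(t.numeric[name][j]))
            w.writerow(row)


def read_survival_labels(path: str | Path, delimiter: str | None = None) -> SurvivalLabels:
    rows = _read_table(path, delimiter)
    header = [h.strip() for h in rows[0]]
    try:
        si, ti, ei = header.index("sample_id"), header.index("time"), header.index("event")
    except ValueError:
        raise ValueError(f"{path}: survival file needs columns sample_id, time, event") from None
    ids = [r[si] for r in rows[1:]]
    time = [float(r[ti]) for r in rows[1:]]
    event = [int(r[ei]) for r in rows[1:]]
    return SurvivalLabels(ids, np.asarray(time), np.asarray(event))


def write_survival_labels(s: SurvivalLabels, path: str | Path, delimiter: str | None = None) -> None:
    delimiter = _infer_delimiter(path, delimiter)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["sample_id", "time", "event"])
        for sid, t, e in zip(s.sample_ids, s.time, s.event):
            w.writerow([sid, format(t, ".17g"), int(e)])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def filter_genes(m: ExpressionMatrix, n_train: int) -> ExpressionMatrix:
    """Drop genes that are zero in more than half the training samples or
    have any missing value.

    The zero-majority rule uses a strict inequality (zero-count > n_train/2
    removes the gene; a gene that is zero in exactly half the samples is
    kept) and is evaluated on the raw, pre-log scale.  Gene order is
    preserved, so the operation is idempotent.
    """
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    zero_count = np.sum(m.values == 0.0, axis=1)
    has_missing = np.any(np.isnan(m.values), axis=1)
    keep = (zero_count <= n_train / 2.0) & ~has_missing
    if not np.any(keep):
        raise ValueError("gene filtering removed every gene")
    kept = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(kept, list(m.sample_ids), m.values[keep, :])


def log_normalize(m: ExpressionMatrix, base: str = "log2") -> ExpressionMatrix:
    """Replace every entry x by log(x + 1) in the requested base (default log2)."""
    if base not in LOG_BASES:
        raise ValueError(f"unknown log base {base!r}; choose from {sorted(LOG_BASES)}")
    if np.any(np.isnan(m.values)):
        raise ValueError("matrix contains missing values; run filter_genes first")
    if np.any(m.values < 0):
        raise ValueError("negative expression value encountered; expected raw counts >= 0")
    values = np.log1p(m.values) / LOG_BASES[base]
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), values)


@dataclass
class Preprocessor:
    """Fitted preprocessing state: everything needed to transform new data.

    Applying a fitted Preprocessor never consults statistics of the data
    being transformed — only what was recorded at fit time on the
    training partition.
    """

    categorical_vocab: dict[str, list[str]] = field(default_factory=dict)
    numeric_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    kept_genes: dict[str, list[str]] = field(default_factory=dict)
    log_base: str = "log2"

    def to_json(self) -> str:
        payload = {
            "categorical_vocab": self.categorical_vocab,
            "numeric_stats": {k: list(v) for k, v in self.numeric_stats.items()},
            "kept_genes": self.kept_genes,
            "log_base": self.log_base,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Preprocessor":
        d = json.loads(text)
        return cls(
            categorical_vocab={k: list(v) for k, v in d["categorical_vocab"].items()},
            numeric_stats={k: (float(v[0]), float(v[1])) for k, v in d["numeric_stats"].items()},
            kept_genes={k: list(v) for k, v in d["kept_genes"].items()},
            log_base=d["log_base"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Preprocessor":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def digest(self) -> str:
        """SHA-256 of the canonical JSON form (used by leakage-guard tests)."""
        return hashlib.sha256(self.to_json().encode("utf-8")).hexdigest()


def fit_clinical_encoder(t: ClinicalTable) -> Preprocessor:
    """Fit one-hot vocabularies and numeric standardisation on training data.

    Category vocabularies keep first-seen order and reserve a final
    "unknown" slot for categories never seen in training (and for missing
    values).  Numeric variables record mean and standard deviation
    (population formula); a zero-variance variable gets sd 1 with a
    warning so z-scoring stays defined.
    """
    prep = Preprocessor()
    for name, labels in t.categorical.items():
        vocab: list[str] = []
        for lab in labels:
            if lab is not None and lab not in vocab:
                vocab.append(lab)
        if not vocab:
            warnings.warn(f"categorical variable {name!r} has no observed categories", stacklevel=2)
        vocab.append(UNKNOWN)
        prep.categorical_vocab[name] = vocab
    for name, values in t.numeric.items():
        finite = values[~np.isnan(values)]
        if finite.size == 0:
            warnings.warn(f"numeric variable {name!r} is entirely missing; using mean 0, sd 1", stacklevel=2)
            prep.numeric_stats[name] = (0.0, 1.0)
            continue
        mean = float(np.mean(finite))
        sd = float(np.std(finite))
        if sd == 0.0:
            warnings.warn(f"numeric variable {name!r} has zero variance; using sd 1", stacklevel=2)
            sd = 1.0
        prep.numeric_stats[name] = (mean, sd)
    return prep


def encode_clinical(t: ClinicalTable, prep: Preprocessor) -> FeatureMatrix:
    """Encode a clinical table with a fitted Preprocessor.

    Per sample: one-hot blocks (unseen or missing category -> the
    reserved unknown slot) concatenated with z-scored numerics, in the
    fixed variable order declared at fit time.
    """
    n = t.n_samples
    feature_names: list[str] = []
    blocks: list[np.ndarray] = []
    for name, vocab in prep.categorical_vocab.items():
        if name not in t.categorical:
            raise ValueError(f"categorical variable {name!r} missing from table")
        labels = t.categorical[name]
        block = np.zeros((len(vocab), n))
        slot = {lab: i for i, lab in enumerate(vocab)}
        unknown_slot = len(vocab) - 1
        for j, lab in enumerate(labels):
            block[slot.get(lab, unknown_slot) if lab is not None else unknown_slot, j] = 1.0
        feature_names.extend(f"{name}={lab}" for lab in vocab)
        blocks.append(block)
    for name, (mean, sd) in prep.numeric_stats.items():
        if name not in t.numeric:
            raise ValueError(f"numeric variable {name!r} missing from table")
        z = (t.numeric[name] - mean) / sd
        z = np.where(np.isnan(z), 0.0, z)  # missing numeric -> training mean
        feature_names.append(name)
        blocks.append(z[None, :])
    values = np.vstack(blocks) if blocks else np.zeros((0, n))
    return FeatureMatrix(feature_names, list(t.sample_ids), values)


def fit_preprocessor(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    clinical: ClinicalTable | None,
    log_base: str = "log2",
) -> Preprocessor:
    """Fit the full preprocessing state on a training partition."""
    prep = Preprocessor(log_base=log_base)
    prep.kept_genes["mrna"] = filter_genes(mrna, mrna.n_samples).gene_ids
    prep.kept_genes["mirna"] = filter_genes(mirna, mirna.n_samples).gene_ids
    if clinical is not None:
        enc = fit_clinical_encoder(clinical)
        prep.categorical_vocab = enc.categorical_vocab
        prep.numeric_stats = enc.numeric_stats
    return prep


def transform_cohort(
    prep: Preprocessor,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    clinical: ClinicalTable | None,
    sample_ids: Sequence[str] | None = None,
) -> dict:
    """Apply a fitted Preprocessor to (train or held-out) data.

    Returns a dict with sample-major arrays ready for the model:
    ``{"mrna": (s, p_m), "mirna": (s, p_mi), "clinical": (s, p_c),
    "feature_ids": {...}, "sample_ids": [...]}``.
    """
    if sample_ids is None:
        sample_ids = list(mrna.sample_ids)
    sample_ids = list(sample_ids)
    out: dict = {"sample_ids": sample_ids, "feature_ids": {}}
    for name, mat in (("mrna", mrna), ("mirna", mirna)):
        sub = mat.subset_genes(prep.kept_genes[name]).subset_samples(sample_ids)
        sub = log_normalize(sub, prep.log_base)
        out[name] = sub.values.T.copy()
        out["feature_ids"][name] = list(sub.gene_ids)
    if clinical is not None:
        fm = encode_clinical(clinical.subset(sample_ids), prep)
        out["clinical"] = fm.values.T.copy()
        out["feature_ids"]["clinical"] = list(fm.feature_names)
    else:
        out["clinical"] = np.zeros((len(sample_ids), 0))
        out["feature_ids"]["clinical"] = []
    return out
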