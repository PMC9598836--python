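"""The prognosis-estimation network: gene attention, residual sub-models,
tanh output heads and ensemble averaging.

Architecture
------------
Each data type (mRNA, miRNA, clinical) passes through its own
squeeze-and-excitation gene-attention layer: two stacked linear maps
p -> q -> p (q << p) with ReLU then sigmoid produce a per-feature gate
``a`` in (0, 1); the layer's output is ``a * x`` componentwise.  The
attended streams are concatenated (mRNA ‖ miRNA ‖ clinical) and fed to
an ensemble of identically structured sub-models that differ only in
their random initialization.  A sub-model is two residual blocks in
series (widths 16 then 8 per block, layer normalisation before each
activation, dropout after, learned linear skip projection whenever the
input width differs from the block output) followed by a 1-unit head
with a hyperbolic tangent, so each score lies in (-1, 1) with higher
values meaning longer expected survival.  The ensemble prediction is
the arithmetic mean of the sub-model scores.

Implementation note: the sub-model bank is stored *stacked* — every
weight carries a leading ensemble axis of length n — so one batched
matrix product evaluates all sub-models at once.  A single sub-model or
residual block is simply the n == 1 case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .autodiff import Tensor, astensor, concat
from .config import ModelConfig

__all__ = [
    "AttentionLayer",
    "ResidualBlock",
    "SubModel",
    "MultiPENModel",
    "attention_forward",
    "fuse_modalities",
    "residual_block_forward",
    "submodel_forward",
    "ensemble_predict",
    "init_model",
    "layer_norm",
    "save_checkpoint",
    "load_checkpoint",
]

MODALITIES = ("mrna", "mirna", "clinical")


def layer_norm(x: Tensor, gain: Tensor, shift: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last (feature) axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * gain + shift


def _dropout(x: Tensor, rate: float, training: bool, rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


@dataclass
class AttentionLayer:
    """Squeeze-and-excitation feature gate: a = sigmoid(W2 relu(W1 x + b1) + b2)."""

    w1: Tensor  # (q, p) squeeze
    b1: Tensor  # (q,)
    w2: Tensor  # (p, q) excitation
    b2: Tensor  # (p,)

    @property
    def p(self) -> int:
        return self.w1.shape[1]

    @property
    def q(self) -> int:
        return self.w1.shape[0]

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: (batch, p).  Returns (attended (batch, p), attention (batch, p))."""
        if x.shape[-1] != self.p:
            raise ValueError(f"attention layer expects {self.p} features, got {x.shape[-1]}")
        h = (x @ self.w1.swap_last() + self.b1).relu()
        a = (h @ self.w2.swap_last() + self.b2).sigmoid()
        return a * x, a

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Attention values for a sample-major numpy batch (batch, p)."""
        return self.forward(Tensor(np.atleast_2d(x)))[1].data

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


def attention_forward(layer: AttentionLayer, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one attention layer on a single sample vector of length p."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("attention_forward expects a 1-D sample vector")
    attended, a = layer.forward(Tensor(x[None, :]))
    return attended.data[0], a.data[0]


def fuse_modalities(xm: np.ndarray, xmi: np.ndarray, xc: np.ndarray) -> np.ndarray:
    """Concatenate attended streams in the fixed order mRNA, miRNA, clinical."""
    parts = [np.atleast_1d(np.asarray(p, dtype=np.float64)) for p in (xm, xmi, xc)]
    return np.concatenate(parts, axis=-1)


@dataclass
class ResidualBlock:
    """A stacked residual block: out = skip(x) + relu(LN2(W2 drop(relu(LN1(W1 x))))).

    All weights carry a leading ensemble axis n; weights are stored
    input-major, i.e. ``w1`` has shape (n, d_in, hidden).
    """

    w1: Tensor  # (n, d_in, hidden)
    b1: Tensor  # (n, 1, hidden)
    ln1_gain: Tensor  # (n, 1, hidden)
    ln1_shift: Tensor  # (n, 1, hidden)
    w2: Tensor  # (n, hidden, out)
    b2: Tensor  # (n, 1, out)
    ln2_gain: Tensor  # (n, 1, out)
    ln2_shift: Tensor  # (n, 1, out)
    skip: Tensor | None  # (n, d_in, out); None = identity (requires d_in == out)
    dropout: float = 0.5
    eps: float = 1e-5

    @property
    def n(self) -> int:
        return self.w1.shape[0]

    @property
    def d_in(self) -> int:
        return self.w1.shape[1]

    @property
    def d_out(self) -> int:
        return self.w2.shape[2]

    def forward(self, x: Tensor, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """x: (1 or n, batch, d_in) -> (n, batch, d_out)."""
        if x.shape[-1] != self.d_in:
            raise ValueError(f"residual block expects {self.d_in} inputs, got {x.shape[-1]}")
        h = layer_norm(x @ self.w1 + self.b1, self.ln1_gain, self.ln1_shift, self.eps).relu()
        h = _dropout(h, self.dropout, training, rng)
        f = layer_norm(h @ self.w2 + self.b2, self.ln2_gain, self.ln2_shift, self.eps).relu()
        out = (x if self.skip is None else x @ self.skip) + f
        if np.isnan(out.data).any():
            raise RuntimeError("NaN in residual block output: invalid weights or inputs")
        return out

    def parameters(self) -> list[Tensor]:
        ps = [self.w1, self.b1, self.ln1_gain, self.ln1_shift, self.w2, self.b2, self.ln2_gain, self.ln2_shift]
        if self.skip is not None:
            ps.append(self.skip)
        return ps

    def view(self, i: int) -> "ResidualBlock":
        """A no-copy view of sub-model i (leading axis length 1)."""
        sl = lambda t: None if t is None else Tensor(t.data[i : i + 1])
        return ResidualBlock(
            sl(self.w1), sl(self.b1), sl(self.ln1_gain), sl(self.ln1_shift),
            sl(self.w2), sl(self.b2), sl(self.ln2_gain), sl(self.ln2_shift),
            sl(self.skip), self.dropout, self.eps,
        )


@dataclass
class SubModel:
    """Two residual blocks in series plus a tanh output head (stacked over n)."""

    block1: ResidualBlock
    block2: ResidualBlock
    head_w: Tensor  # (n, d, 1)
    head_b: Tensor  # (n, 1, 1)

    @property
    def n(self) -> int:
        return self.block1.n

    @property
    def d_in(self) -> int:
        return self.block1.d_in

    def forward(
        self,
        x: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
        squash: bool = True,
    ) -> Tensor:
        """x: (1 or n, batch, d_in) -> scores (n, batch).

        With ``squash`` (the default) scores pass through the tanh head
        and lie in (-1, 1); ``squash=False`` returns the raw pre-tanh
        scores, which share the same ordering (tanh is monotone) and are
        what the ranking objective trains on.
        """
        h = self.block1.forward(x, training, rng)
        h = self.block2.forward(h, training, rng)
        y = h @ self.head_w + self.head_b
        if squash:
            y = y.tanh()
        n, b = y.shape[0], y.shape[1]
        return y.reshape(n, b)

    def parameters(self) -> list[Tensor]:
        return self.block1.parameters() + self.block2.parameters() + [self.head_w, self.head_b]

    def view(self, i: int) -> "SubModel":
        return SubModel(
            self.block1.view(i),
            self.block2.view(i),
            Tensor(self.head_w.data[i : i + 1]),
            Tensor(self.head_b.data[i : i + 1]),
        )


def residual_block_forward(
    block: ResidualBlock,
    x: np.ndarray,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate a single (n == 1) residual block on one sample vector."""
    if block.n != 1:
        raise ValueError("residual_block_forward expects a single block; use .view(i) on a bank")
    x = np.asarray(x, dtype=np.float64)
    out = block.forward(Tensor(x[None, None, :]), training=(mode == "train"), rng=rng)
    return out.data[0, 0]


def submodel_forward(
    m: SubModel,
    fused: np.ndarray,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> float:
    """Evaluate a single (n == 1) sub-model on one fused sample vector."""
    if m.n != 1:
        raise ValueError("submodel_forward expects a single sub-model; use .view(i) on a bank")
    fused = np.asarray(fused, dtype=np.float64)
    out = m.forward(Tensor(fused[None, None, :]), training=(mode == "train"), rng=rng)
    return float(out.data[0, 0])


@dataclass
class MultiPENModel:
    """Shared per-datatype attention layers feeding a stacked sub-model ensemble."""

    attention_mrna: AttentionLayer
    attention_mirna: AttentionLayer
    attention_clinical: AttentionLayer | None
    bank: SubModel
    fusion_order: tuple[str, ...] = MODALITIES
    seed: int | None = None

    @property
    def n_submodels(self) -> int:
        return self.bank.n

    @property
    def submodels(self) -> list[SubModel]:
        return [self.bank.view(i) for i in range(self.bank.n)]

    def attention_layer(self, modality: str) -> AttentionLayer | None:
        return {
            "mrna": self.attention_mrna,
            "mirna": self.attention_mirna,
            "clinical": self.attention_clinical,
        }[modality]

    def forward(
        self,
        batch: Mapping[str, np.ndarray | Tensor],
        training: bool = False,
        rng: np.random.Generator | None = None,
        squash: bool = True,
    ) -> Tensor:
        """batch: modality -> (samples, features) arrays (shared sample order).

        Returns the per-sub-model score matrix as a Tensor of shape
        (n_submodels, samples); see SubModel.forward for ``squash``.
        """
        attended: list[Tensor] = []
        for modality in self.fusion_order:
            layer = self.attention_layer(modality)
            if layer is None:
                continue
            x = astensor(batch[modality])
            out, _ = layer.forward(x)
            attended.append(out)
        fused = attended[0] if len(attended) == 1 else concat(attended, axis=-1)
        b, d = fused.shape
        return self.bank.forward(fused.reshape(1, b, d), training=training, rng=rng, squash=squash)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in (self.attention_mrna, self.attention_mirna, self.attention_clinical):
            if layer is not None:
                ps.extend(layer.parameters())
        ps.extend(self.bank.parameters())
        return [p for p in ps if p.requires_grad]


def ensemble_predict(
    model: MultiPENModel, batch: Mapping[str, np.ndarray], squash: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode prediction.

    Returns (ensemble mean per sample, per-sub-model score matrix of
    shape (n_submodels, samples)).  The ensemble prediction is the
    arithmetic mean over sub-models.  ``squash=False`` returns the raw
    pre-tanh scores, which order samples identically but cannot
    collide at the tanh's saturation plateaus; rank-based evaluation
    uses those.
    """
    if model.n_submodels == 0:
        raise ValueError("ensemble has no sub-models")
    scores = model.forward(batch, training=False, squash=squash).data
    return scores.mean(axis=0), scores


# ---------------------------------------------------------------------------
# initialization and checkpointing
# ---------------------------------------------------------------------------


def _he_uniform(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _param(data: np.ndarray, trainable: bool = True) -> Tensor:
    return Tensor(data, requires_grad=trainable)


def _init_attention(rng: np.random.Generator, p: int, q: int, use_bias: bool) -> AttentionLayer:
    # The excitation (second) layer starts at zero so every gate opens at
    # exactly sigmoid(0) = 0.5: gates then move only under systematic
    # gradient pressure, which is what makes the learned attention values
    # interpretable as feature importance rather than frozen init noise.
    return AttentionLayer(
        w1=_param(_he_uniform(rng, p, (q, p))),
        b1=_param(np.zeros(q), trainable=use_bias),
        w2=_param(np.zeros((p, q))),
        b2=_param(np.zeros(p), trainable=use_bias),
    )


def _init_block(
    rng: np.random.Generator, n: int, d_in: int, hidden: int, out: int,
    dropout: float, eps: float, use_bias: bool,
) -> ResidualBlock:
    skip = None
    if d_in != out:
        skip = _param(_he_uniform(rng, d_in, (n, d_in, out)))
    return ResidualBlock(
        w1=_param(_he_uniform(rng, d_in, (n, d_in, hidden))),
        b1=_param(np.zeros((n, 1, hidden)), trainable=use_bias),
        ln1_gain=_param(np.ones((n, 1, hidden))),
        ln1_shift=_param(np.zeros((n, 1, hidden))),
        w2=_param(_he_uniform(rng, hidden, (n, hidden, out))),
        b2=_param(np.zeros((n, 1, out)), trainable=use_bias),
        ln2_gain=_param(np.ones((n, 1, out))),
        ln2_shift=_param(np.zeros((n, 1, out))),
        skip=skip,
        dropout=dropout,
        eps=eps,
    )


def init_model(
    config: ModelConfig,
    p_mrna: int,
    p_mirna: int,
    p_clinical: int = 0,
    seed: int = 0,
) -> MultiPENModel:
    """Build a freshly initialized model.

    Weights use fan-in-scaled uniform (He-style) initialization drawn
    from a generator seeded with `seed`; the same seed always yields a
    bitwise-identical model.  ``p_clinical`` may be 0, in which case the
    clinical stream is absent.
    """
    if config.n_submodels <= 0:
        raise ValueError("ensemble size must be positive")
    if p_mrna <= 0 or p_mirna <= 0 or p_clinical < 0:
        raise ValueError("feature counts must be positive (clinical may be 0)")
    rng = np.random.default_rng(seed)
    q = config.attention_bottleneck
    att_m = _init_attention(rng, p_mrna, q, config.use_bias)
    att_mi = _init_attention(rng, p_mirna, q, config.use_bias)
    att_c = _init_attention(rng, p_clinical, q, config.use_bias) if p_clinical > 0 else None
    d_fused = p_mrna + p_mirna + p_clinical
    hidden, out = config.block_widths
    n = config.n_submodels
    block1 = _init_block(rng, n, d_fused, hidden, out, config.dropout, config.layer_norm_eps, config.use_bias)
    block2 = _init_block(rng, n, out, hidden, out, config.dropout, config.layer_norm_eps, config.use_bias)
    bank = SubModel(
        block1=block1,
        block2=block2,
        head_w=_param(_he_uniform(rng, out, (n, out, 1))),
        head_b=_param(np.zeros((n, 1, 1)), trainable=config.use_bias),
    )
    return MultiPENModel(att_m, att_mi, att_c, bank, MODALITIES, seed=seed)


def _weights_dict(model: MultiPENModel) -> dict:
    d: dict = {}
    for name in ("mrna", "mirna", "clinical"):
        layer = model.attention_layer(name)
        if layer is None:
            continue
        d[f"attention_{name}"] = {
            "w1": layer.w1.data.tolist(), "b1": layer.b1.data.tolist(),
            "w2": layer.w2.data.tolist(), "b2": layer.b2.data.tolist(),
        }
    for bname, block in (("block1", model.bank.block1), ("block2", model.bank.block2)):
        d[bname] = {
            "w1": block.w1.data.tolist(), "b1": block.b1.data.tolist(),
            "ln1_gain": block.ln1_gain.data.tolist(), "ln1_shift": block.ln1_shift.data.tolist(),
            "w2": block.w2.data.tolist(), "b2": block.b2.data.tolist(),
            "ln2_gain": block.ln2_gain.data.tolist(), "ln2_shift": block.ln2_shift.data.tolist(),
            "skip": None if block.skip is None else block.skip.data.tolist(),
            "dropout": block.dropout, "eps": block.eps,
        }
    d["head"] = {"w": model.bank.head_w.data.tolist(), "b": model.bank.head_b.data.tolist()}
    return d


def save_checkpoint(model: MultiPENModel, config: ModelConfig, path: str | Path) -> None:
    """Serialize model weights + config to a single JSON checkpoint file."""
    payload = {
        "format": "multipen-checkpoint-v1",
        "config": config.to_dict(),
        "fusion_order": list(model.fusion_order),
        "seed": model.seed,
        "weights": _weights_dict(model),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_checkpoint(path: str | Path) -> tuple[MultiPENModel, ModelConfig]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "multipen-checkpoint-v1":
        raise ValueError(f"{path}: not a recognized checkpoint file")
    config = ModelConfig.from_dict(payload["config"])
    w = payload["weights"]

    def att(name: str) -> AttentionLayer | None:
        if name not in w:
            return None
        a = w[name]
        return AttentionLayer(
            _param(np.asarray(a["w1"])), _param(np.asarray(a["b1"]), config.use_bias),
            _param(np.asarray(a["w2"])), _param(np.asarray(a["b2"]), config.use_bias),
        )

    def block(name: str) -> ResidualBlock:
        b = w[name]
        return ResidualBlock(
            _param(np.asarray(b["w1"])), _param(np.asarray(b["b1"]), config.use_bias),
            _param(np.asarray(b["ln1_gain"])), _param(np.asarray(b["ln1_shift"])),
            _param(np.asarray(b["w2"])), _param(np.asarray(b["b2"]), config.use_bias),
            _param(np.asarray(b["ln2_gain"])), _param(np.asarray(b["ln2_shift"])),
            None if b["skip"] is None else _param(np.asarray(b["skip"])),
            b["dropout"], b["eps"],
        )

    bank = SubModel(
        block("block1"), block("block2"),
        _param(np.asarray(w["head"]["w"])), _param(np.asarray(w["head"]["b"]), config.use_bias),
    )
    model = MultiPENModel(
        att("attention_mrna"), att("attention_mirna"), att("attention_clinical"),
        bank, tuple(payload["fusion_order"]), seed=payload.get("seed"),
    )
    return model, config
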