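"""Forward-pass oracles for attention, residual blocks, sub-models, ensemble."""

import numpy as np
import pytest

from multipen.autodiff import Tensor
from multipen.config import ModelConfig
from multipen.model import (
    AttentionLayer,
    ResidualBlock,
    SubModel,
    attention_forward,
    ensemble_predict,
    fuse_modalities,
    init_model,
    residual_block_forward,
    submodel_forward,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def make_attention(w1, b1, w2, b2):
    return AttentionLayer(Tensor(w1), Tensor(b1), Tensor(w2), Tensor(b2))


class TestAttentionLayer:
    def test_zero_weights_gate_everything_at_half(self):
        layer = make_attention(np.zeros((2, 4)), np.zeros(2), np.zeros((4, 2)), np.zeros(4))
        x = np.array([1.0, -2.0, 3.0, 0.5])
        attended, a = attention_forward(layer, x)
        np.testing.assert_allclose(a, 0.5)
        np.testing.assert_allclose(attended, 0.5 * x)

    def test_hand_computed_two_gene_example(self):
        # p=2, q=1: W_A1=[[1,0]], W_A2=[[1],[-1]], zero biases, x=(1,0)
        # hidden = relu(1*1 + 0*0) = 1; logits = (1, -1)
        # a = (sigmoid(1), sigmoid(-1)); attended = a * x = (sigmoid(1), 0)
        layer = make_attention(np.array([[1.0, 0.0]]), np.zeros(1), np.array([[1.0], [-1.0]]), np.zeros(2))
        attended, a = attention_forward(layer, np.array([1.0, 0.0]))
        np.testing.assert_allclose(a, [0.7310585786300049, 0.2689414213699951], atol=1e-12)
        np.testing.assert_allclose(attended, [0.7310585786300049, 0.0], atol=1e-12)

    def test_attention_strictly_inside_unit_interval(self):
        # strict in exact arithmetic; float64 saturates only for |logit| > ~36,
        # so moderate inputs exercise the property without rounding artifacts
        rng = np.random.default_rng(0)
        layer = make_attention(
            rng.normal(scale=0.5, size=(3, 8)), rng.normal(size=3),
            rng.normal(scale=0.5, size=(8, 3)), rng.normal(size=8),
        )
        for _ in range(20):
            _, a = attention_forward(layer, rng.normal(size=8))
            assert np.all(a > 0.0) and np.all(a < 1.0)

    def test_attended_magnitude_never_exceeds_input(self):
        rng = np.random.default_rng(1)
        layer = make_attention(
            rng.normal(size=(3, 8)), rng.normal(size=3), rng.normal(size=(8, 3)), rng.normal(size=8)
        )
        x = rng.normal(scale=3.0, size=8)
        attended, _ = attention_forward(layer, x)
        assert np.all(np.abs(attended) <= np.abs(x))

    def test_dimension_mismatch_reports_expected_size(self):
        layer = make_attention(np.zeros((2, 4)), np.zeros(2), np.zeros((4, 2)), np.zeros(4))
        with pytest.raises(ValueError, match="4"):
            attention_forward(layer, np.ones(5))


class TestFuseModalities:
    def test_lengths_and_order(self):
        xm, xmi, xc = np.arange(5.0), np.arange(3.0) + 10, np.arange(2.0) + 20
        fused = fuse_modalities(xm, xmi, xc)
        assert fused.shape == (10,)
        np.testing.assert_array_equal(fused[:5], xm)
        np.testing.assert_array_equal(fused[5:8], xmi)

    def test_empty_clinical_stream(self):
        fused = fuse_modalities(np.ones(4), np.ones(2), np.zeros(0))
        assert fused.shape == (6,)


def zero_block(n, d_in, hidden, out, skip_identity=True):
    skip = None if skip_identity else Tensor(np.zeros((n, d_in, out)))
    return ResidualBlock(
        w1=Tensor(np.zeros((n, d_in, hidden))),
        b1=Tensor(np.zeros((n, 1, hidden))),
        ln1_gain=Tensor(np.ones((n, 1, hidden))),
        ln1_shift=Tensor(np.zeros((n, 1, hidden))),
        w2=Tensor(np.zeros((n, hidden, out))),
        b2=Tensor(np.zeros((n, 1, out))),
        ln2_gain=Tensor(np.ones((n, 1, out))),
        ln2_shift=Tensor(np.zeros((n, 1, out))),
        skip=skip,
        dropout=0.5,
    )


def oracle_block(x, w1, b1, w2, b2, skip, eps=1e-5):
    """Independent scalar re-implementation of the residual block (eval mode)."""

    def ln(v):
        mu = v.mean()
        var = ((v - mu) ** 2).mean()
        return (v - mu) / np.sqrt(var + eps)

    h = np.maximum(0.0, ln(w1 @ x + b1))
    f = np.maximum(0.0, ln(w2 @ h + b2))
    base = x if skip is None else skip @ x
    return base + f


class TestResidualBlock:
    def test_zero_inner_path_is_identity(self):
        block = zero_block(1, 8, 16, 8)
        x = np.arange(8.0) - 3.0
        np.testing.assert_array_equal(residual_block_forward(block, x), x)

    def test_small_integer_block_matches_independent_oracle(self):
        # d_in=2, hidden=3, out=2 with small integer weights, eval mode
        w1 = np.array([[1.0, -1.0], [2.0, 0.0], [0.0, 1.0]])
        b1 = np.array([0.0, 1.0, -1.0])
        w2 = np.array([[1.0, 0.0, 2.0], [-1.0, 1.0, 0.0]])
        b2 = np.array([1.0, 0.0])
        skip = np.array([[2.0, 0.0], [0.0, 3.0]])
        block = ResidualBlock(
            w1=Tensor(w1.T[None]), b1=Tensor(b1[None, None]),
            ln1_gain=Tensor(np.ones((1, 1, 3))), ln1_shift=Tensor(np.zeros((1, 1, 3))),
            w2=Tensor(w2.T[None]), b2=Tensor(b2[None, None]),
            ln2_gain=Tensor(np.ones((1, 1, 2))), ln2_shift=Tensor(np.zeros((1, 1, 2))),
            skip=Tensor(skip.T[None]), dropout=0.5,
        )
        x = np.array([1.5, -0.5])
        np.testing.assert_allclose(
            residual_block_forward(block, x), oracle_block(x, w1, b1, w2, b2, skip), atol=1e-6
        )

    def test_eval_mode_deterministic(self):
        rng = np.random.default_rng(2)
        cfg = ModelConfig()
        model = init_model(cfg, 5, 4, 3, seed=8)
        block = model.bank.block1.view(0)
        x = rng.normal(size=block.d_in)
        first = residual_block_forward(block, x)
        second = residual_block_forward(block, x)
        np.testing.assert_array_equal(first, second)

    def test_nan_input_is_hard_error(self):
        block = zero_block(1, 8, 16, 8)
        with pytest.raises(RuntimeError, match="NaN"):
            residual_block_forward(block, np.full(8, np.nan))


class TestSubModel:
    def submodel_fixed(self):
        w1 = np.array([[1.0, -1.0], [0.5, 0.5], [2.0, 0.0]])
        b1 = np.array([0.0, 0.5, -0.5])
        w2 = np.array([[1.0, 1.0, 0.0], [0.0, -1.0, 1.0]])
        b2 = np.array([0.5, -0.5])
        skip1 = np.array([[1.0, 2.0], [0.0, 1.0]])
        w3 = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        b3 = np.array([0.0, 0.0, 1.0])
        w4 = np.array([[1.0, -1.0, 0.5], [2.0, 0.0, 0.0]])
        b4 = np.array([0.0, 1.0])
        head_w = np.array([0.5, -1.0])
        head_b = 0.25
        block1 = ResidualBlock(
            Tensor(w1.T[None]), Tensor(b1[None, None]),
            Tensor(np.ones((1, 1, 3))), Tensor(np.zeros((1, 1, 3))),
            Tensor(w2.T[None]), Tensor(b2[None, None]),
            Tensor(np.ones((1, 1, 2))), Tensor(np.zeros((1, 1, 2))),
            Tensor(skip1.T[None]), 0.5,
        )
        block2 = ResidualBlock(
            Tensor(w3.T[None]), Tensor(b3[None, None]),
            Tensor(np.ones((1, 1, 3))), Tensor(np.zeros((1, 1, 3))),
            Tensor(w4.T[None]), Tensor(b4[None, None]),
            Tensor(np.ones((1, 1, 2))), Tensor(np.zeros((1, 1, 2))),
            None, 0.5,
        )
        sub = SubModel(block1, block2, Tensor(head_w[None, :, None]), Tensor(np.full((1, 1, 1), head_b)))
        weights = (w1, b1, w2, b2, skip1, w3, b3, w4, b4, head_w, head_b)
        return sub, weights

    def test_fixed_weights_match_independent_oracle(self):
        sub, (w1, b1, w2, b2, skip1, w3, b3, w4, b4, head_w, head_b) = self.submodel_fixed()
        x = np.array([0.75, -1.25])
        h1 = oracle_block(x, w1, b1, w2, b2, skip1)
        h2 = oracle_block(h1, w3, b3, w4, b4, None)
        expected = np.tanh(head_w @ h2 + head_b)
        np.testing.assert_allclose(submodel_forward(sub, x), expected, atol=1e-6)

    def test_zero_head_outputs_zero(self):
        sub, _ = self.submodel_fixed()
        sub.head_w.data[:] = 0.0
        sub.head_b.data[:] = 0.0
        assert submodel_forward(sub, np.array([1.0, 2.0])) == 0.0

    def test_output_strictly_inside_tanh_range(self):
        sub, _ = self.submodel_fixed()
        rng = np.random.default_rng(3)
        for _ in range(25):
            y = submodel_forward(sub, rng.normal(scale=10.0, size=2))
            assert -1.0 < y < 1.0


class TestEnsemble:
    def batch(self, model, rng):
        return {
            "mrna": rng.normal(size=(6, model.attention_mrna.p)),
            "mirna": rng.normal(size=(6, model.attention_mirna.p)),
            "clinical": rng.normal(size=(6, model.attention_clinical.p)),
        }

    def test_mean_matches_external_average_of_submodels(self):
        model = init_model(ModelConfig(), 7, 5, 3, seed=4)
        rng = np.random.default_rng(4)
        batch = self.batch(model, rng)
        mean, per = ensemble_predict(model, batch)
        assert per.shape == (10, 6)
        np.testing.assert_allclose(mean, per.mean(axis=0), rtol=1e-6)
        # per-sub-model scores recomputed through the single-model views agree
        from multipen.autodiff import concat

        attended = []
        for modality in model.fusion_order:
            out, _ = model.attention_layer(modality).forward(Tensor(batch[modality]))
            attended.append(out.data)
        fused = np.concatenate(attended, axis=-1)
        for i, sub in enumerate(model.submodels):
            for j in range(6):
                np.testing.assert_allclose(submodel_forward(sub, fused[j]), per[i, j], atol=1e-12)

    def test_identical_submodels_collapse_to_single_output(self):
        model = init_model(ModelConfig(n_submodels=4), 6, 4, 0, seed=9)
        bank = model.bank
        for t in bank.parameters():
            t.data[:] = t.data[0:1]  # copy sub-model 0 into all
        rng = np.random.default_rng(5)
        batch = {"mrna": rng.normal(size=(3, 6)), "mirna": rng.normal(size=(3, 4))}
        mean, per = ensemble_predict(model, batch)
        np.testing.assert_allclose(per, np.broadcast_to(per[0], per.shape), atol=1e-12)
        np.testing.assert_allclose(mean, per[0], atol=1e-12)

    def test_constant_opposite_heads_cancel(self):
        model = init_model(ModelConfig(n_submodels=2), 6, 4, 0, seed=9)
        bank = model.bank
        bank.head_w.data[:] = 0.0
        bank.head_b.data[0] = 1.0
        bank.head_b.data[1] = -1.0
        rng = np.random.default_rng(6)
        batch = {"mrna": rng.normal(size=(3, 6)), "mirna": rng.normal(size=(3, 4))}
        mean, per = ensemble_predict(model, batch)
        np.testing.assert_allclose(per[0], np.tanh(1.0))
        np.testing.assert_allclose(per[1], -np.tanh(1.0))
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)


class TestInitModel:
    def test_default_dimensions_follow_study_configuration(self):
        model = init_model(ModelConfig(), 20, 10, 5, seed=0)
        assert model.n_submodels == 10
        for layer in (model.attention_mrna, model.attention_mirna, model.attention_clinical):
            assert layer.q == 10
        assert model.bank.block1.w1.shape == (10, 35, 16)
        assert model.bank.block1.w2.shape == (10, 16, 8)
        assert model.bank.block2.d_in == 8

    def test_same_seed_bitwise_identical(self):
        a = init_model(ModelConfig(), 6, 4, 2, seed=7)
        b = init_model(ModelConfig(), 6, 4, 2, seed=7)
        for ta, tb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(ta.data, tb.data)

    def test_different_seeds_differ(self):
        a = init_model(ModelConfig(), 6, 4, 2, seed=7)
        b = init_model(ModelConfig(), 6, 4, 2, seed=8)
        assert any(not np.array_equal(ta.data, tb.data) for ta, tb in zip(a.parameters(), b.parameters()))

    def test_nonpositive_ensemble_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_submodels=0)

    def test_clinical_stream_may_be_absent(self):
        model = init_model(ModelConfig(), 6, 4, 0, seed=1)
        assert model.attention_clinical is None
        rng = np.random.default_rng(0)
        mean, _ = ensemble_predict(model, {"mrna": rng.normal(size=(2, 6)), "mirna": rng.normal(size=(2, 4))})
        assert mean.shape == (2,)


class TestForwardProperties:
    def test_eval_forward_bitwise_reproducible(self):
        model = init_model(ModelConfig(), 9, 5, 4, seed=12)
        rng = np.random.default_rng(12)
        batch = {
            "mrna": rng.normal(size=(5, 9)),
            "mirna": rng.normal(size=(5, 5)),
            "clinical": rng.normal(size=(5, 4)),
        }
        a, _ = ensemble_predict(model, batch)
        b, _ = ensemble_predict(model, batch)
        np.testing.assert_array_equal(a, b)

    def test_forcing_gate_closed_removes_gene_sensitivity(self):
        # drive one gene's pre-sigmoid logit to -inf: the model output must
        # become insensitive to that gene (finite-difference ~ 0)
        model = init_model(ModelConfig(n_submodels=3), 8, 4, 0, seed=2)
        gene = 3
        model.attention_mrna.w2.data[gene, :] = 0.0
        model.attention_mrna.b2.data[gene] = -1e9
        rng = np.random.default_rng(2)
        batch = {"mrna": rng.normal(size=(1, 8)), "mirna": rng.normal(size=(1, 4))}
        base, _ = ensemble_predict(model, batch)
        bumped = {k: v.copy() for k, v in batch.items()}
        bumped["mrna"][0, gene] += 1.0
        moved, _ = ensemble_predict(model, bumped)
        assert abs(moved[0] - base[0]) <= 1e-6

    def test_checkpoint_round_trip(self, tmp_path):
        from multipen.model import load_checkpoint, save_checkpoint

        cfg = ModelConfig(n_submodels=3)
        model = init_model(cfg, 6, 4, 2, seed=3)
        path = tmp_path / "model.json"
        save_checkpoint(model, cfg, path)
        back, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        rng = np.random.default_rng(3)
        batch = {
            "mrna": rng.normal(size=(4, 6)),
            "mirna": rng.normal(size=(4, 4)),
            "clinical": rng.normal(size=(4, 2)),
        }
        a, _ = ensemble_predict(model, batch)
        b, _ = ensemble_predict(back, batch)
        np.testing.assert_array_equal(a, b)
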