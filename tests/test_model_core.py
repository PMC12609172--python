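"""Model blocks against straight-line numpy oracles and structural invariants."""

import numpy as np
import pytest

from dsadeepfm.autodiff import Tensor
from dsadeepfm.model import (
    DSABlock, DSADeepFMNetwork, EmbeddingAttention, FMLayer, FieldAttention,
    ModelConfig, expected_parameter_count,
)
from dsadeepfm.training import weighted_cross_entropy
from dsadeepfm.nn import Adam

E = 4


def _softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def field_attention_oracle(attn, x_cat, x_num):
    """Per-field projection, concat, 2-way softmax, residual rescale."""
    B, F, _ = x_cat.shape
    oc, on, sc = np.empty_like(x_cat), np.empty_like(x_num), np.empty((B, F, 2))
    for b in range(B):
        for i in range(F):
            hc = x_cat[b, i] @ attn.W_cat.data + attn.b_cat.data
            hn = x_num[b, i] @ attn.W_num.data + attn.b_num.data
            s = _softmax(np.concatenate([hc, hn]) @ attn.W_field.data + attn.b_field.data)
            sc[b, i] = s
            oc[b, i] = x_cat[b, i] * s[0] + x_cat[b, i]
            on[b, i] = x_num[b, i] * s[1] + x_num[b, i]
    return oc, on, sc


def embedding_attention_oracle(attn, x_cat, x_num):
    """Transpose, per-dimension projection, 2-way softmax, residual rescale."""
    B, F, Edim = x_cat.shape
    tc, tn = x_cat.transpose(0, 2, 1), x_num.transpose(0, 2, 1)
    oc, on = np.empty_like(tc), np.empty_like(tn)
    sc = np.empty((B, Edim, 2))
    for b in range(B):
        for j in range(Edim):
            hc = tc[b, j] @ attn.W_cat.data + attn.b_cat.data
            hn = tn[b, j] @ attn.W_num.data + attn.b_num.data
            s = _softmax(np.concatenate([hc, hn]) @ attn.W_emb.data + attn.b_emb.data)
            sc[b, j] = s
            oc[b, j] = tc[b, j] * s[0] + tc[b, j]
            on[b, j] = tn[b, j] * s[1] + tn[b, j]
    return oc, on, sc


class TestFieldAttention:
    def test_scores_sum_to_one_and_match_oracle(self, rng):
        attn = FieldAttention(rng, E)
        x_cat = rng.normal(size=(2, 3, E))
        x_num = rng.normal(size=(2, 3, E))
        oc, on, s = attn(Tensor(x_cat), Tensor(x_num))
        np.testing.assert_allclose(s.data.sum(axis=-1), 1.0, atol=1e-6)
        ec, en, es = field_attention_oracle(attn, x_cat, x_num)
        np.testing.assert_allclose(oc.data, ec, atol=1e-6)
        np.testing.assert_allclose(on.data, en, atol=1e-6)
        np.testing.assert_allclose(s.data, es, atol=1e-6)

    def test_zero_scorer_gives_exact_half_scores_and_1p5x_residual(self, rng):
        attn = FieldAttention(rng, E)
        attn.W_field.data[:] = 0.0
        attn.b_field.data[:] = 0.0
        x = rng.normal(size=(1, 3, E))
        oc, on, s = attn(Tensor(x), Tensor(x.copy()))
        np.testing.assert_array_equal(s.data, 0.5)
        np.testing.assert_allclose(oc.data, 1.5 * x, atol=1e-12)

    def test_residual_keeps_row_norm_between_1x_and_2x(self, rng):
        attn = FieldAttention(rng, E)
        x_cat = rng.normal(size=(3, 3, E))
        x_num = rng.normal(size=(3, 3, E))
        oc, on, _ = attn(Tensor(x_cat), Tensor(x_num))
        for out, inp in ((oc.data, x_cat), (on.data, x_num)):
            n_in = np.linalg.norm(inp, axis=-1)
            n_out = np.linalg.norm(out, axis=-1)
            assert np.all(n_out > n_in) and np.all(n_out < 2 * n_in)


class TestEmbeddingAttention:
    def test_scores_sum_to_one_and_match_oracle(self, rng):
        attn = EmbeddingAttention(rng, 3)
        x_cat = rng.normal(size=(2, 3, E))
        x_num = rng.normal(size=(2, 3, E))
        oc, on, s = attn(Tensor(x_cat), Tensor(x_num))
        np.testing.assert_allclose(s.data.sum(axis=-1), 1.0, atol=1e-6)
        ec, en, es = embedding_attention_oracle(attn, x_cat, x_num)
        np.testing.assert_allclose(oc.data, ec, atol=1e-6)
        np.testing.assert_allclose(on.data, en, atol=1e-6)
        np.testing.assert_allclose(s.data, es, atol=1e-6)

    def test_zero_scorer_gives_1p5x_residual(self, rng):
        attn = EmbeddingAttention(rng, 3)
        attn.W_emb.data[:] = 0.0
        attn.b_emb.data[:] = 0.0
        x = rng.normal(size=(1, 3, E))
        oc, _, s = attn(Tensor(x), Tensor(x.copy()))
        np.testing.assert_array_equal(s.data, 0.5)
        np.testing.assert_allclose(oc.data, 1.5 * x.transpose(0, 2, 1), atol=1e-12)


class TestDSABlock:
    def test_output_length_composition_and_zero_propagation(self, rng):
        dsa = DSABlock(rng, E, n_fields=3)
        x_cat = rng.normal(size=(2, 3, E))
        x_num = rng.normal(size=(2, 3, E))
        out = dsa(Tensor(x_cat), Tensor(x_num))
        assert out.shape == (2, 6 * E)
        # composition: field stage then embedding stage, flattened field-major
        fc, fn, _ = dsa.field_attn(Tensor(x_cat), Tensor(x_num))
        tc, tn, _ = dsa.emb_attn(fc, fn)
        manual = np.concatenate(
            [tc.data.transpose(0, 2, 1).reshape(2, -1),
             tn.data.transpose(0, 2, 1).reshape(2, -1)], axis=1
        )
        np.testing.assert_allclose(out.data, manual, atol=1e-12)
        zero = dsa(Tensor(np.zeros((1, 3, E))), Tensor(np.zeros((1, 3, E))))
        np.testing.assert_array_equal(zero.data, 0.0)


class TestFM:
    def brute_force(self, x, W, V):
        first = x @ W
        second = np.zeros(V.shape[1])
        for i in range(len(x)):
            for j in range(i + 1, len(x)):
                second += (V[i] * V[j]) * x[i] * x[j]
        return first + second

    def test_zero_and_single_coordinate(self, rng):
        fm = FMLayer(rng, 12, 5)
        np.testing.assert_allclose(fm(Tensor(np.zeros((1, 12)))).data, 0.0, atol=1e-12)
        x = np.zeros((1, 12))
        x[0, 4] = 2.5
        out = fm(Tensor(x))
        np.testing.assert_allclose(out.data[0], x[0] @ fm.W.data, atol=1e-10)

    def test_efficient_form_equals_brute_force(self, rng):
        fm = FMLayer(rng, 12, 5)
        for _ in range(20):
            x = rng.normal(size=12)
            got = fm(Tensor(x[None, :])).data[0]
            want = self.brute_force(x, fm.W.data, fm.V.data)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)


def _tiny_net(**overrides):
    kw = dict(E=E, K=6, dnn_widths=(5, 6), hidden_pred=7, dropout=0.0, seed=0)
    kw.update(overrides)
    cfg = ModelConfig(**kw)
    net = DSADeepFMNetwork(cfg, n_entities=10, num_input_dim=14)
    net.set_training(False)
    return net, cfg


class TestNetwork:
    def test_embedding_lookup_identity_and_sharing(self, rng):
        net, _ = _tiny_net()
        cat = np.array([[0, 3, 8], [0, 5, 9]])
        emb = net.embed_categorical(cat).data
        np.testing.assert_array_equal(emb[0, 0], net.embedding.table.data[0])
        np.testing.assert_array_equal(emb[0, 1], net.embedding.table.data[3])
        np.testing.assert_array_equal(emb[0, 0], emb[1, 0])  # shared drug1

    def test_out_of_range_index_raises(self):
        net, _ = _tiny_net()
        with pytest.raises(IndexError, match="entity index"):
            net.embed_categorical(np.array([[0, 1, 99]]))

    def test_extract_numerical_oracle_and_shape(self, rng):
        net, cfg = _tiny_net()
        x = rng.normal(size=(2, 14))
        got = net.extract_numerical(x).data
        assert got.shape == (2, 3, cfg.E)
        h = np.maximum(x @ net.extract1.W.data + net.extract1.b.data, 0.0)
        want = (h @ net.extract2.W.data + net.extract2.b.data).reshape(2, 3, cfg.E)
        np.testing.assert_allclose(got, want, atol=1e-10)
        # zero input with zero biases (and zero weights) -> zero output
        net.extract1.b.data[:] = 0
        net.extract2.b.data[:] = 0
        net.extract2.W.data[:] = 0
        np.testing.assert_array_equal(
            net.extract_numerical(np.zeros((1, 14))).data, 0.0
        )
        with pytest.raises(ValueError, match="expected 14"):
            net.extract_numerical(np.zeros((1, 9)))

    def test_dnn_sigmoid_range_and_zero_weights_half(self, rng):
        net, cfg = _tiny_net()
        x = rng.normal(size=(3, 6 * E))
        out = net.dnn(Tensor(x)).data
        assert np.all(out > 0) and np.all(out < 1)
        for layer in (net.dnn.fc1, net.dnn.fc2):
            layer.W.data[:] = 0
            layer.b.data[:] = 0
        np.testing.assert_array_equal(net.dnn(Tensor(x)).data, 0.5)

    def test_head_probabilities_sum_to_one_and_match_oracle(self, rng):
        net, cfg = _tiny_net()
        D = cfg.fused_dim
        y_fm = rng.normal(size=(2, cfg.K))
        y_dnn = rng.normal(size=(2, cfg.K))
        x = rng.normal(size=(2, D))
        probs = net.head(Tensor(y_fm), Tensor(y_dnn), Tensor(x)).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0) and np.all(probs < 1)

        # straight-line oracle: eval-mode batchnorm (running stats), fusion,
        # projection, head dual-stage attention, two dense layers, softmax
        def bn(v, mod):
            mu = mod._buffers["running_mean"]
            sd = np.sqrt(mod._buffers["running_var"] + mod.eps)
            return (v - mu) / sd * mod.gamma.data + mod.beta.data

        fused = np.concatenate([bn(y_fm, net.head.bn_fm), bn(y_dnn, net.head.bn_dnn)], axis=1)
        xt1 = _sigmoid(fused @ net.head.proj.W.data + net.head.proj.b.data)
        res = net.head.res_attn
        F = net.head.n_blocks
        b1 = x.reshape(2, F, cfg.E)
        b2 = xt1.reshape(2, F, cfg.E)
        fc1, fc2_, _ = field_attention_oracle(res.field_attn, b1, b2)
        t1, t2, _ = embedding_attention_oracle(res.emb_attn, fc1, fc2_)
        x_attn = np.concatenate(
            [t1.transpose(0, 2, 1).reshape(2, -1), t2.transpose(0, 2, 1).reshape(2, -1)],
            axis=1,
        )
        h = _sigmoid(x_attn @ net.head.fc2.W.data + net.head.fc2.b.data)
        logits = _sigmoid(h @ net.head.fc3.W.data + net.head.fc3.b.data)
        want = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs, want, atol=1e-5)

    def test_forward_probability_valid_and_eval_deterministic(self, rng):
        net, _ = _tiny_net(dropout=0.3)
        cat = np.array([[0, 1, 8], [2, 3, 9]])
        num = rng.normal(size=(2, 14))
        p1 = net.predict_proba(cat, num)
        p2 = net.predict_proba(cat, num)
        np.testing.assert_array_equal(p1, p2)
        assert np.all(p1 > 0) and np.all(p1 < 1)

    def test_all_zero_inputs_give_finite_probability(self):
        net, _ = _tiny_net()
        net.embedding.table.data[:] = 0.0
        p = net.predict_proba(np.array([[0, 1, 9]]), np.zeros((1, 14)))
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p.sum(), 1.0, atol=1e-9)

    def test_single_training_step_decreases_loss(self, rng):
        net, cfg = _tiny_net()
        net.set_training(True)
        cat = np.array([[0, 1, 8]])
        num = rng.normal(size=(1, 14))
        y = np.array([1])

        def loss_value():
            return weighted_cross_entropy(net.forward(cat, num), y)

        opt = Adam(net.parameters(), lr=1e-3)
        before = loss_value()
        before.backward()
        opt.step()
        after = loss_value()
        assert after.item() < before.item()

    def test_frozen_embeddings_unchanged_by_training_step(self, rng):
        net, _ = _tiny_net(freeze_embeddings=True)
        net.set_training(True)
        snapshot = net.embedding.table.data.copy()
        cat = np.array([[0, 1, 8], [2, 3, 9]])
        num = rng.normal(size=(2, 14))
        loss = weighted_cross_entropy(net.forward(cat, num), np.array([1, 0]))
        opt = Adam(net.parameters(), lr=1e-2)
        loss.backward()
        opt.step()
        np.testing.assert_array_equal(net.embedding.table.data, snapshot)

    @pytest.mark.parametrize("overrides", [
        {},
        {"use_numerical": False},
        {"use_categorical": False},
        {"attention_mode": "unified"},
        {"residual_mode": "dense3", "dense3_widths": (9, 5)},
        {"fusion_mode": "gated_sum"},
        {"fusion_mode": "gated_concat"},
        {"attention_mode": "field_only"},
        {"attention_mode": "emb_only"},
    ])
    def test_parameter_count_matches_closed_form(self, overrides):
        net, cfg = _tiny_net(**overrides)
        assert net.n_parameters() == expected_parameter_count(cfg, 10, 14)

    def test_checkpoint_roundtrip_is_bit_exact(self, tmp_path, rng):
        net, _ = _tiny_net(dropout=0.2)
        cat = np.array([[0, 1, 8], [4, 2, 9]])
        num = rng.normal(size=(2, 14))
        before = net.predict_proba(cat, num)
        path = tmp_path / "model.npz"
        net.save(path)
        back = DSADeepFMNetwork.load(path)
        np.testing.assert_array_equal(back.predict_proba(cat, num), before)

    def test_config_contract_violations(self):
        with pytest.raises(ValueError, match="must equal"):
            ModelConfig(E=4, K=8, dnn_widths=(4, 6))
        with pytest.raises(ValueError, match="attention_mode"):
            ModelConfig(E=4, K=6, dnn_widths=(4, 6), attention_mode="bogus")
        with pytest.raises(ValueError, match="one input stream"):
            ModelConfig(E=4, K=6, dnn_widths=(4, 6),
                        use_categorical=False, use_numerical=False)
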