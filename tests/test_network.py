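"""Network building blocks against independent scalar oracles."""

import math

import numpy as np
import pytest

import asircast as ac
from asircast import autodiff as ad
from asircast.autodiff import Tensor
from asircast.network import (attention_head, bilstm_forward, ensemble_predict,
                              group_heads, input_projection, lstm_cell_step,
                              multi_scale_attention, residual_fusion, scale_mask,
                              _lstm_direction)
from conftest import build_pipeline


def sigmoid_s(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def dot(v, w) -> float:
    return sum(a * b for a, b in zip(v, w))


def mat_vec_T(M, v):
    """Row-vector times matrix: (v @ M) as plain lists."""
    return [dot(v, [M[i][j] for i in range(len(M))]) for j in range(len(M[0]))]


class TestInputProjection:
    def test_zero_weights_give_zero(self, rng):
        X = rng.standard_normal((2, 4, 3))
        out = input_projection(Tensor(X), Tensor(np.zeros((3, 5))), Tensor(np.zeros(5)))
        assert np.all(out.data == 0)

    def test_relu_kills_negative_bias(self, rng):
        X = rng.random((2, 4, 3))
        W = Tensor(rng.standard_normal((3, 5)) * 0.01)
        out = input_projection(Tensor(X), W, Tensor(np.full(5, -100.0)))
        assert np.all(out.data == 0)

    def test_matches_affine_relu_oracle(self, rng):
        X = rng.standard_normal((3, 4, 6))
        W = rng.standard_normal((6, 5))
        b = rng.standard_normal(5)
        out = input_projection(Tensor(X), Tensor(W), Tensor(b))
        expected = np.maximum(X @ W + b, 0.0)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            input_projection(Tensor(rng.random((1, 2, 3))),
                             Tensor(np.zeros((4, 5))), Tensor(np.zeros(5)))


def random_cell_weights(rng, d_in, d_h):
    w = {}
    for gate in ("f", "i", "C", "o"):
        w[f"W_{gate}"] = Tensor(rng.standard_normal((d_h + d_in, d_h)))
        w[f"b_{gate}"] = Tensor(rng.standard_normal(d_h))
    return w


class TestLstmCell:
    def test_zero_weights_zero_state(self):
        d_in, d_h = 3, 2
        w = {f"W_{g}": Tensor(np.zeros((d_h + d_in, d_h))) for g in "fiCo"}
        w.update({f"b_{g}": Tensor(np.zeros(d_h)) for g in "fiCo"})
        h, c = lstm_cell_step(Tensor(np.ones((1, d_in))), Tensor(np.zeros((1, d_h))),
                              Tensor(np.zeros((1, d_h))), w)
        assert np.all(h.data == 0) and np.all(c.data == 0)

    def test_saturated_forget_gate_preserves_cell(self, rng):
        d_in, d_h = 3, 2
        w = {f"W_{g}": Tensor(np.zeros((d_h + d_in, d_h))) for g in "fiCo"}
        w.update({f"b_{g}": Tensor(np.zeros(d_h)) for g in "fiCo"})
        w["b_f"] = Tensor(np.full(d_h, 50.0))  # forget gate ~= 1
        w["b_i"] = Tensor(np.full(d_h, -50.0))  # input gate ~= 0
        c_prev = rng.standard_normal((1, d_h))
        _, c = lstm_cell_step(Tensor(rng.standard_normal((1, d_in))),
                              Tensor(np.zeros((1, d_h))), Tensor(c_prev), w)
        np.testing.assert_allclose(c.data, c_prev, atol=1e-9)

    def test_matches_scalar_oracle(self, rng):
        """Straight-line scalar implementation of the six gate equations."""
        d_in, d_h = 4, 3
        w = random_cell_weights(rng, d_in, d_h)
        x = rng.standard_normal(d_in)
        h_prev = rng.standard_normal(d_h)
        c_prev = rng.standard_normal(d_h)

        z = list(h_prev) + list(x)
        f = [sigmoid_s(v + b) for v, b in zip(mat_vec_T(w["W_f"].data, z), w["b_f"].data)]
        i = [sigmoid_s(v + b) for v, b in zip(mat_vec_T(w["W_i"].data, z), w["b_i"].data)]
        c_tilde = [math.tanh(v + b) for v, b in zip(mat_vec_T(w["W_C"].data, z), w["b_C"].data)]
        c_new = [f[j] * c_prev[j] + i[j] * c_tilde[j] for j in range(d_h)]
        o = [sigmoid_s(v + b) for v, b in zip(mat_vec_T(w["W_o"].data, z), w["b_o"].data)]
        h_new = [o[j] * math.tanh(c_new[j]) for j in range(d_h)]

        h, c = lstm_cell_step(Tensor(x[None, :]), Tensor(h_prev[None, :]),
                              Tensor(c_prev[None, :]), w)
        np.testing.assert_allclose(h.data[0], h_new, atol=1e-6)
        np.testing.assert_allclose(c.data[0], c_new, atol=1e-6)

    def test_gate_boundedness(self, rng):
        """Sigmoid gates stay in (0,1), tanh in (-1,1), for wild inputs."""
        x = rng.standard_normal((100,)) * 10  # wild but below float saturation
        s = ad.sigmoid(Tensor(x)).data
        t = ad.tanh(Tensor(x)).data
        assert np.all((s > 0) & (s < 1))
        assert np.all((t >= -1) & (t <= 1))


class TestBiLstm:
    def test_single_step_window(self, rng):
        d_h = 2
        layer = {"forward": random_cell_weights(rng, 3, d_h),
                 "backward": random_cell_weights(rng, 3, d_h)}
        H = Tensor(rng.standard_normal((2, 1, 3)))
        out = bilstm_forward(H, [layer], d_h)
        h_f, _ = lstm_cell_step(H[:, 0, :], Tensor(np.zeros((2, d_h))),
                                Tensor(np.zeros((2, d_h))), layer["forward"])
        h_b, _ = lstm_cell_step(H[:, 0, :], Tensor(np.zeros((2, d_h))),
                                Tensor(np.zeros((2, d_h))), layer["backward"])
        np.testing.assert_allclose(out.data[:, 0, :d_h], h_f.data, atol=1e-12)
        np.testing.assert_allclose(out.data[:, 0, d_h:], h_b.data, atol=1e-12)

    def test_time_reversal_swaps_directions(self, rng):
        d_h = 3
        w = random_cell_weights(rng, 4, d_h)
        H = Tensor(rng.standard_normal((2, 6, 4)))
        H_rev = Tensor(H.data[:, ::-1, :].copy())
        fwd_on_rev = _lstm_direction(H_rev, w, d_h, reverse=False)
        bwd_on_orig = _lstm_direction(H, w, d_h, reverse=True)
        for t in range(6):
            np.testing.assert_allclose(fwd_on_rev[t].data, bwd_on_orig[5 - t].data,
                                       atol=1e-12)

    def test_eval_mode_deterministic(self, rng):
        d_h = 2
        layer = {"forward": random_cell_weights(rng, 3, d_h),
                 "backward": random_cell_weights(rng, 3, d_h)}
        H = Tensor(rng.standard_normal((2, 5, 3)))
        a = bilstm_forward(H, [layer], d_h, dropout=0.5, training=False)
        b = bilstm_forward(H, [layer], d_h, dropout=0.5, training=False)
        np.testing.assert_array_equal(a.data, b.data)


class TestAttention:
    def _head_params(self, rng, width, d_a):
        return (Tensor(rng.standard_normal((width, d_a))), Tensor(rng.standard_normal(d_a)),
                Tensor(rng.standard_normal((d_a, 1))))

    def test_single_step_mask_returns_that_step(self, rng):
        W_a, b_a, v_a = self._head_params(rng, 4, 3)
        H = Tensor(rng.standard_normal((2, 5, 4)))
        mask = np.array([False, False, True, False, False])
        ctx, w = attention_head(H, W_a, b_a, v_a, 3, mask)
        np.testing.assert_allclose(ctx.data, H.data[:, 2, :], atol=1e-12)
        np.testing.assert_allclose(w.data[:, 2, 0], 1.0)

    def test_identical_steps_give_uniform_weights(self, rng):
        W_a, b_a, v_a = self._head_params(rng, 4, 3)
        h = rng.standard_normal(4)
        H = Tensor(np.tile(h, (1, 6, 1)))
        mask = np.array([True, True, True, False, False, True])
        _, w = attention_head(H, W_a, b_a, v_a, 3, mask)
        np.testing.assert_allclose(w.data[0, mask, 0], 0.25, atol=1e-12)
        np.testing.assert_allclose(w.data[0, ~mask, 0], 0.0)

    def test_matches_brute_force_oracle(self, rng):
        W_a, b_a, v_a = self._head_params(rng, 4, 3)
        H = rng.standard_normal((2, 5, 4))
        mask = np.array([True, False, True, True, False])
        ctx, _ = attention_head(Tensor(H), W_a, b_a, v_a, 3, mask)
        for b in range(2):
            logits = []
            for t in range(5):
                s = np.tanh(W_a.data.T @ H[b, t] + b_a.data)
                logits.append(float(s @ v_a.data[:, 0]) / math.sqrt(3))
            logits = np.array(logits)
            w = np.where(mask, np.exp(logits), 0.0)
            w = w / w.sum()
            expected = sum(w[t] * H[b, t] for t in range(5))
            np.testing.assert_allclose(ctx.data[b], expected, atol=1e-6)

    def test_weights_sum_to_one_and_zero_on_masked(self, rng):
        W_a, b_a, v_a = self._head_params(rng, 6, 4)
        H = Tensor(rng.standard_normal((3, 10, 6)))
        mask = scale_mask(10, 3, 6)
        _, w = attention_head(H, W_a, b_a, v_a, 4, mask)
        np.testing.assert_allclose(w.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(w.data[:, ~mask, :] == 0)

    def test_empty_mask_rejected(self, rng):
        W_a, b_a, v_a = self._head_params(rng, 4, 3)
        with pytest.raises(ValueError):
            attention_head(Tensor(rng.standard_normal((1, 5, 4))), W_a, b_a, v_a, 3,
                           np.zeros(5, dtype=bool))


class TestScaleMask:
    def test_default_scales_cover_expected_lags(self):
        assert scale_mask(10, 1, 3).tolist() == [False] * 7 + [True] * 3
        assert scale_mask(10, 6, 10).tolist() == [True] * 5 + [False] * 5
        # boundary lags 3 and 6 belong to both adjacent scales
        assert scale_mask(10, 1, 3)[7] and scale_mask(10, 3, 6)[7]
        assert scale_mask(10, 3, 6)[4] and scale_mask(10, 6, 10)[4]


class TestMultiScaleAttention:
    def test_context_width(self, tiny_model):
        X = np.random.default_rng(0).standard_normal((2, 3, 6))
        H = tiny_model.forward(Tensor(X))  # smoke: full forward works
        hp = tiny_model.hp
        Hseq = Tensor(np.random.default_rng(1).standard_normal((2, 3, 2 * hp.d_h)))
        C = multi_scale_attention(Hseq, tiny_model.attn_params, hp, window=3)
        assert C.shape == (2, 3 * 2 * hp.d_h)

    def test_width_for_dh_64(self):
        hp = ac.Hyperparameters(d_h=64, n_lstm_layers=1)
        model = ac.DualPathwayModel(n_features=12, n_groups=4, window=10, hp=hp, seed=0)
        Hseq = Tensor(np.random.default_rng(2).standard_normal((1, 10, 128)))
        C = multi_scale_attention(Hseq, model.attn_params, hp, window=10)
        assert C.shape == (1, 384)

    def test_perturbing_fully_masked_step_leaves_context_unchanged(self, rng):
        hp = ac.Hyperparameters(d_h=2, n_lstm_layers=1, heads_per_scale=2,
                                scales=((1, 3), (2, 3), (1, 2)), batchnorm=False)
        model = ac.DualPathwayModel(n_features=4, n_groups=2, window=10, hp=hp, seed=3)
        Hseq = rng.standard_normal((2, 10, 4))
        C1 = multi_scale_attention(Tensor(Hseq), model.attn_params, hp, window=10)
        Hseq2 = Hseq.copy()
        Hseq2[:, :7, :] += 100.0  # lags 4..10: outside every scale
        C2 = multi_scale_attention(Tensor(Hseq2), model.attn_params, hp, window=10)
        np.testing.assert_array_equal(C1.data, C2.data)

    def test_identical_heads_equal_single_head_through_projection(self, rng):
        hp = ac.Hyperparameters(d_h=3, n_lstm_layers=1, heads_per_scale=4,
                                scales=((1, 5),), batchnorm=False)
        model = ac.DualPathwayModel(n_features=4, n_groups=2, window=5, hp=hp, seed=7)
        ref = model.attn_params["scale0_head0"]
        for hj in range(1, 4):
            for k in ("W_a", "b_a", "v_a"):
                model.attn_params[f"scale0_head{hj}"][k].data = ref[k].data.copy()
        Hseq = Tensor(rng.standard_normal((2, 5, 6)))
        C = multi_scale_attention(Hseq, model.attn_params, hp, window=5)
        ctx, _ = attention_head(Hseq, ref["W_a"], ref["b_a"], ref["v_a"], hp.d_a,
                                scale_mask(5, 1, 5))
        W = model.attn_params["scale0_proj"]["W"].data
        b = model.attn_params["scale0_proj"]["b"].data
        block_sum = sum(W[i * 6:(i + 1) * 6] for i in range(4))
        np.testing.assert_allclose(C.data, ctx.data @ block_sum + b, atol=1e-9)


class TestGroupHeads:
    def _params(self, rng, d_in, d_shared, G):
        return {"W_shared": Tensor(rng.standard_normal((d_in, d_shared))),
                "b_shared": Tensor(rng.standard_normal(d_shared)),
                "W_groups": Tensor(rng.standard_normal((d_shared, G))),
                "b_groups": Tensor(rng.standard_normal(G))}

    def test_zero_weights_give_bias(self, rng):
        p = self._params(rng, 4, 3, 5)
        p["W_groups"] = Tensor(np.zeros((3, 5)))
        out = group_heads(Tensor(rng.standard_normal((2, 4))), p)
        np.testing.assert_allclose(out.data, np.tile(p["b_groups"].data, (2, 1)))

    def test_identical_heads_identical_predictions(self, rng):
        p = self._params(rng, 4, 3, 2)
        p["W_groups"].data[:, 1] = p["W_groups"].data[:, 0]
        p["b_groups"].data[1] = p["b_groups"].data[0]
        out = group_heads(Tensor(rng.standard_normal((3, 4))), p)
        np.testing.assert_allclose(out.data[:, 0], out.data[:, 1])

    def test_matches_per_group_loop_oracle(self, rng):
        p = self._params(rng, 4, 3, 5)
        C = rng.standard_normal((3, 4))
        out = group_heads(Tensor(C), p)
        H_shared = np.maximum(C @ p["W_shared"].data + p["b_shared"].data, 0.0)
        for g in range(5):
            expected = H_shared @ p["W_groups"].data[:, g] + p["b_groups"].data[g]
            np.testing.assert_allclose(out.data[:, g], expected, atol=1e-10)

    def test_width_mismatch_rejected(self, rng):
        p = self._params(rng, 4, 3, 5)
        p["W_groups"] = Tensor(np.zeros((7, 5)))
        with pytest.raises(ValueError):
            group_heads(Tensor(rng.standard_normal((2, 4))), p)


class TestResidualFusion:
    def test_alpha_one_is_deep_only(self, rng):
        X = rng.standard_normal((2, 4, 3))
        y_deep = Tensor(rng.standard_normal((2, 5)))
        W = Tensor(rng.standard_normal((3, 5)))
        fused, deep, res, alpha = residual_fusion(Tensor(X), y_deep, W, Tensor(30.0))
        np.testing.assert_allclose(fused.data, y_deep.data, atol=1e-9)
        assert float(alpha.data) == pytest.approx(1.0, abs=1e-9)

    def test_alpha_zero_is_pure_linear(self, rng):
        X = rng.standard_normal((2, 4, 3))
        y_deep = Tensor(rng.standard_normal((2, 5)))
        W = Tensor(rng.standard_normal((3, 5)))
        fused, _, _, _ = residual_fusion(Tensor(X), y_deep, W, Tensor(-30.0))
        np.testing.assert_allclose(fused.data, X.mean(axis=1) @ W.data, atol=1e-9)

    def test_constant_in_time_average(self, rng):
        row = rng.standard_normal(3)
        X = np.tile(row, (2, 4, 1))
        W = Tensor(np.eye(3))
        fused, _, _, _ = residual_fusion(Tensor(X), Tensor(np.zeros((2, 3))), W,
                                         Tensor(-30.0))
        np.testing.assert_allclose(fused.data, np.tile(row, (2, 1)), atol=1e-9)


class _Stub:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full((len(X), 2), self.value, dtype=float)


class TestEnsemble:
    def test_single_member_identity(self):
        X = np.zeros((3, 4, 5))
        np.testing.assert_allclose(ensemble_predict([_Stub(2.0)], X), 2.0)

    def test_identical_members(self):
        X = np.zeros((3, 4, 5))
        np.testing.assert_allclose(ensemble_predict([_Stub(1.5)] * 3, X), 1.5)

    def test_arithmetic_mean(self):
        X = np.zeros((3, 4, 5))
        out = ensemble_predict([_Stub(0.0), _Stub(1.0), _Stub(2.0)], X)
        np.testing.assert_allclose(out, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], np.zeros((1, 2, 3)))


class TestFullModelScalarOracle:
    def test_matches_straight_line_implementation(self, tiny_model, rng):
        """Scalar reimplementation of the whole forward pass (eval mode)."""
        model = tiny_model
        hp = model.hp
        d_h, T, D, G = hp.d_h, 3, 6, 2
        X = rng.standard_normal((1, T, D))
        got = model.forward(Tensor(X)).data[0]

        # input projection (no batch norm in the tiny config)
        W_in, b_in = model.params["W_input"].data, model.params["b_input"].data
        H = [[max(v, 0.0) for v in (X[0, t] @ W_in + b_in)] for t in range(T)]

        def run_dir(inputs, w, rev):
            order = list(range(T - 1, -1, -1)) if rev else list(range(T))
            h, c = [0.0] * d_h, [0.0] * d_h
            out = [None] * T
            for t in order:
                z = h + list(inputs[t])
                f = [sigmoid_s(dot(z, w["W_f"].data[:, j]) + w["b_f"].data[j])
                     for j in range(d_h)]
                i = [sigmoid_s(dot(z, w["W_i"].data[:, j]) + w["b_i"].data[j])
                     for j in range(d_h)]
                ct = [math.tanh(dot(z, w["W_C"].data[:, j]) + w["b_C"].data[j])
                      for j in range(d_h)]
                c = [f[j] * c[j] + i[j] * ct[j] for j in range(d_h)]
                o = [sigmoid_s(dot(z, w["W_o"].data[:, j]) + w["b_o"].data[j])
                     for j in range(d_h)]
                h = [o[j] * math.tanh(c[j]) for j in range(d_h)]
                out[t] = h
            return out

        seq = H
        for layer in model.lstm_layers:
            fwd = run_dir(seq, layer["forward"], rev=False)
            bwd = run_dir(seq, layer["backward"], rev=True)
            seq = [fwd[t] + bwd[t] for t in range(T)]

        width = 2 * d_h
        contexts = []
        for si, (lo, hi) in enumerate(hp.scales):
            mask = [lo <= T - t <= hi for t in range(T)]
            heads = []
            for hj in range(hp.heads_per_scale):
                p = model.attn_params[f"scale{si}_head{hj}"]
                logits = []
                for t in range(T):
                    s = [math.tanh(dot(seq[t], p["W_a"].data[:, j]) + p["b_a"].data[j])
                         for j in range(hp.d_a)]
                    logits.append(dot(s, p["v_a"].data[:, 0]) / math.sqrt(hp.d_a))
                ex = [math.exp(l) if m else 0.0 for l, m in zip(logits, mask)]
                tot = sum(ex)
                a = [e / tot for e in ex]
                heads.append([sum(a[t] * seq[t][j] for t in range(T)) for j in range(width)])
            flat = [v for hctx in heads for v in hctx]
            proj = model.attn_params[f"scale{si}_proj"]
            contexts.append([dot(flat, proj["W"].data[:, j]) + proj["b"].data[j]
                             for j in range(width)])
        C = [v for ctx in contexts for v in ctx]

        hp_d = model.head_params
        H_shared = [max(dot(C, hp_d["W_shared"].data[:, j]) + hp_d["b_shared"].data[j], 0.0)
                    for j in range(hp.d_shared)]
        y_deep = [dot(H_shared, hp_d["W_groups"].data[:, g]) + hp_d["b_groups"].data[g]
                  for g in range(G)]

        x_avg = [sum(X[0, t, d] for t in range(T)) / T for d in range(D)]
        W_res = model.params["W_residual"].data
        res = [dot(x_avg, W_res[:, g]) for g in range(G)]
        alpha = sigmoid_s(float(model.params["alpha_raw"].data))
        expected = [alpha * y_deep[g] + (1 - alpha) * res[g] for g in range(G)]

        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestPathwayRecovery:
    def test_alpha_zero_least_squares_linear_autoregression(self):
        """With the deep path off, a fitted linear path nails linear data."""
        spec = ac.SyntheticSpec(seed=11, noise_sd=0.0, trend_kind="linear")
        p = build_pipeline(spec)
        split = p["split"]
        hp = ac.Hyperparameters(d_h=4, n_lstm_layers=1, heads_per_scale=2,
                                batchnorm=False)
        model = ac.DualPathwayModel(n_features=144, n_groups=24, window=10, hp=hp, seed=0)
        model.set_alpha(0.0)
        X_avg = split.train.inputs.mean(axis=1)
        W, *_ = np.linalg.lstsq(X_avg, split.train.targets, rcond=None)
        model.params["W_residual"].data = W
        pred = model.predict(split.test.inputs)
        rep = ac.evaluate(split.test.targets, pred)
        assert rep.r2 >= 0.99


class TestModelPlumbing:
    def test_state_round_trip(self, tiny_model, rng):
        X = rng.standard_normal((2, 3, 6))
        before = tiny_model.predict(X)
        state = tiny_model.state_arrays()
        clone = tiny_model.clone()
        np.testing.assert_array_equal(clone.predict(X), before)
        tiny_model.load_state_arrays(state)
        np.testing.assert_array_equal(tiny_model.predict(X), before)

    def test_alpha_setter(self, tiny_model):
        tiny_model.set_alpha(0.25)
        assert tiny_model.alpha == pytest.approx(0.25, abs=1e-9)

    def test_input_gradient_matches_numeric(self, tiny_model):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, 6))
        _, grad = tiny_model.input_gradient(x, output="sum")
        eps = 1e-6
        for idx in [(0, 0), (1, 3), (2, 5)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fp = tiny_model.predict(xp[None]).sum()
            fm = tiny_model.predict(xm[None]).sum()
            assert grad[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-5)

    def test_non_finite_input_rejected(self, tiny_model):
        X = np.full((1, 3, 6), np.nan)
        with pytest.raises(FloatingPointError):
            tiny_model.forward(Tensor(X))
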