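import numpy as np
import pytest

from conftest import random_symmetric_network
from hetdti.autodiff import Tensor
from hetdti.encoder import (
    EncoderConfig,
    EncoderModel,
    encode,
    extract_attention,
    fuse,
    gat_layer,
    gcn_layer,
    normalized_adjacency,
    train_encoder,
)
from hetdti.hetnet import HeteroNetwork
from oracles import gcn_dense_oracle, uniform_attention_oracle


def _net(H, v, m):
    return HeteroNetwork(drug_ids=[f"d{i}" for i in range(v)],
                         protein_ids=[f"p{i}" for i in range(m)], H=H)


class TestGCN:
    def test_edgeless_identity_propagation(self):
        H = np.zeros((4, 4))
        net = _net(H, 2, 2)
        F = np.arange(16.0).reshape(4, 4)
        out = gcn_layer(net, F, np.eye(4), activate=False)
        np.testing.assert_allclose(out.data, F)

    def test_matches_dense_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = random_symmetric_network(rng, 2, 3)
            F = rng.standard_normal((5, 5))
            W = rng.standard_normal((5, 3))
            out = gcn_layer(net, F, W, activate=True)
            np.testing.assert_allclose(out.data, gcn_dense_oracle(net.H, F, W),
                                       atol=1e-10)

    def test_output_depends_only_on_closed_neighborhood(self):
        # 3-node path graph: node 0's output must ignore node 2's features
        H = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        net = _net(H, 1, 2)
        rng = np.random.default_rng(0)
        F = rng.standard_normal((3, 2))
        W = rng.standard_normal((2, 2))
        base = gcn_layer(net, F, W, activate=False).data[0]
        F2 = F.copy()
        F2[2] += 10.0
        np.testing.assert_allclose(gcn_layer(net, F2, W, activate=False).data[0], base)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        net = random_symmetric_network(rng, 3, 3)
        F = rng.standard_normal((6, 4))
        W = rng.standard_normal((4, 2))
        out = gcn_layer(net, F, W).data
        perm = rng.permutation(6)
        net_p = _net(net.H[np.ix_(perm, perm)], 3, 3)
        out_p = gcn_layer(net_p, F[perm], W).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


def _random_heads(rng, d_in, d_out, k):
    return [
        (Tensor(rng.standard_normal((d_in, d_out)), requires_grad=True),
         Tensor(rng.standard_normal(2 * d_out), requires_grad=True),
         Tensor(rng.standard_normal(()), requires_grad=True))
        for _ in range(k)
    ]


class TestGAT:
    def test_attention_sums_to_one_over_neighborhoods(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_symmetric_network(rng, 3, 4)
            F = rng.standard_normal((7, 6))
            heads = _random_heads(rng, 6, 4, 2)
            _, attn = gat_layer(net, F, heads, 0.2, return_attention=True)
            np.testing.assert_allclose(attn.sum(axis=1), np.ones(7), atol=1e-12)
            assert np.all(attn >= 0.0)

    def test_single_neighbor_gets_full_attention(self):
        H = np.zeros((3, 3))
        H[0, 1] = H[1, 0] = 0.7  # node 0's only neighbor is node 1
        net = _net(H, 1, 2)
        rng = np.random.default_rng(1)
        F = rng.standard_normal((3, 2))
        heads = _random_heads(rng, 2, 2, 1)
        _, attn = gat_layer(net, F, heads, 0.2, return_attention=True)
        assert attn[0, 1] == pytest.approx(1.0)

    def test_uniform_parameters_reduce_to_neighborhood_mean(self):
        rng = np.random.default_rng(2)
        net = random_symmetric_network(rng, 2, 3)
        F = rng.standard_normal((5, 4))
        W = rng.standard_normal((4, 3))
        heads = [(Tensor(W), Tensor(np.zeros(6)), Tensor(np.zeros(())))]
        out = gat_layer(net, F, heads, 0.2)
        np.testing.assert_allclose(out.data, uniform_attention_oracle(net.H, F, W),
                                   atol=1e-12)

    def test_isolated_node_attends_to_itself(self):
        H = np.zeros((3, 3))
        H[1, 2] = H[2, 1] = 1.0  # node 0 isolated
        net = _net(H, 1, 2)
        rng = np.random.default_rng(4)
        F = rng.standard_normal((3, 2))
        heads = _random_heads(rng, 2, 2, 1)
        _, attn = gat_layer(net, F, heads, 0.2, return_attention=True)
        assert attn[0, 0] == pytest.approx(1.0)


class TestEncode:
    def test_trivial_plan_returns_input_blocks(self):
        H = np.zeros((4, 4))
        net = _net(H, 2, 2)
        F = np.abs(np.arange(16.0).reshape(4, 4))
        cfg = EncoderConfig(layer_plan=("gcn",), hidden_dims=(4,), seed=0)
        model = EncoderModel(cfg, in_dim=4)
        model.params["gcn0_W"] = Tensor(np.eye(4), requires_grad=True)
        emb = encode(net, F, model)
        np.testing.assert_allclose(emb.X_D, F[:2])  # ReLU is identity on F >= 0
        np.testing.assert_allclose(emb.X_P, F[2:])

    def test_composition_matches_sequential_layers(self):
        rng = np.random.default_rng(9)
        net = random_symmetric_network(rng, 2, 3)
        F = rng.standard_normal((5, 5))
        cfg = EncoderConfig(layer_plan=("gcn", "gat", "gcn"), hidden_dims=(4, 3, 2),
                            heads=2, seed=7)
        model = EncoderModel(cfg, in_dim=5)
        emb = encode(net, F, model)
        x = gcn_layer(net, F, model.params["gcn0_W"])
        heads = [(model.params["gat1_W0"], model.params["gat1_a0"], model.params["gat1_B0"]),
                 (model.params["gat1_W1"], model.params["gat1_a1"], model.params["gat1_B1"])]
        x = gat_layer(net, x, heads, cfg.leaky_slope)
        x = gcn_layer(net, x, model.params["gcn2_W"])
        np.testing.assert_allclose(np.vstack([emb.X_D, emb.X_P]), x.data, atol=1e-12)

    def test_fuse_concatenates_pairs(self):
        rng = np.random.default_rng(0)
        net = random_symmetric_network(rng, 2, 2)
        cfg = EncoderConfig(layer_plan=("gcn",), hidden_dims=(2,), seed=0)
        emb = encode(net, rng.standard_normal((4, 4)), EncoderModel(cfg, 4))
        Z = fuse(emb, [("d0", "p1"), ("d0", "p0")])
        assert Z.shape == (2, 4)
        np.testing.assert_array_equal(Z[0], np.concatenate([emb.X_D[0], emb.X_P[1]]))
        np.testing.assert_array_equal(Z[0, :2], Z[1, :2])
        assert fuse(emb, []).shape == (0, 4)

    def test_fuse_unknown_id_errors(self):
        rng = np.random.default_rng(0)
        net = random_symmetric_network(rng, 2, 2)
        cfg = EncoderConfig(layer_plan=("gcn",), hidden_dims=(2,), seed=0)
        emb = encode(net, rng.standard_normal((4, 4)), EncoderModel(cfg, 4))
        with pytest.raises(KeyError, match="dZ"):
            fuse(emb, [("dZ", "p0")])


def _train_setup(seed=0):
    rng = np.random.default_rng(seed)
    net = random_symmetric_network(rng, 3, 4)
    F = net.H.copy()
    pairs = [(("d0", "p0"), 1), (("d1", "p1"), 1), (("d2", "p2"), 0), (("d0", "p3"), 0)]
    return net, F, pairs


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        net, F, pairs = _train_setup()
        cfg = EncoderConfig(hidden_dims=(8, 6, 4), heads=2, epochs=60,
                            l2_lambda=0.0, seed=1)
        _, losses = train_encoder(net, F, pairs, cfg)
        assert losses[-1] < losses[0]

    def test_sgd_small_lr_monotone_descent(self):
        net, F, pairs = _train_setup()
        cfg = EncoderConfig(hidden_dims=(8, 6, 4), heads=2, epochs=50,
                            optimizer="sgd", lr=1e-3, dropout=0.0, seed=1)
        _, losses = train_encoder(net, F, pairs, cfg)
        diffs = np.diff(losses)
        assert np.all(diffs <= 1e-6)

    def test_seeded_runs_bit_identical(self):
        net, F, pairs = _train_setup()
        cfg = EncoderConfig(hidden_dims=(8, 6, 4), heads=2, epochs=20, seed=5)
        m1, l1 = train_encoder(net, F, pairs, cfg)
        m2, l2 = train_encoder(net, F, pairs, cfg)
        assert l1 == l2
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)

    def test_huge_l2_drives_weights_to_zero(self):
        net, F, pairs = _train_setup()
        small = EncoderConfig(hidden_dims=(8, 6, 4), heads=2, epochs=80,
                              optimizer="sgd", lr=1e-3, l2_lambda=0.0, seed=1)
        big = EncoderConfig(hidden_dims=(8, 6, 4), heads=2, epochs=80,
                            optimizer="sgd", lr=1e-3, l2_lambda=100.0, seed=1)
        m_small, _ = train_encoder(net, F, pairs, small)
        m_big, _ = train_encoder(net, F, pairs, big)
        norm = lambda m: sum(float((t.data**2).sum()) for t in m.params.values())
        assert norm(m_big) < 0.01 * norm(m_small)

    def test_single_class_errors(self):
        net, F, _ = _train_setup()
        pairs = [(("d0", "p0"), 1), (("d1", "p1"), 1)]
        with pytest.raises(ValueError, match="both classes"):
            train_encoder(net, F, pairs, EncoderConfig(hidden_dims=(4, 4, 4), seed=0))


class TestAttentionExtraction:
    def test_weights_nonneg_and_sum_to_one(self):
        net, F, pairs = _train_setup(3)
        cfg = EncoderConfig(hidden_dims=(8, 6, 4), heads=2, epochs=10, seed=2)
        model, _ = train_encoder(net, F, pairs, cfg)
        wd, wp = extract_attention(model, net, F, ("d0", "p1"))
        for w in (wd, wp):
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0.0)

    def test_plan_without_gat_errors(self):
        net, F, pairs = _train_setup()
        cfg = EncoderConfig(layer_plan=("gcn",), hidden_dims=(4,), seed=0)
        model = EncoderModel(cfg, in_dim=7)
        with pytest.raises(ValueError, match="no GAT"):
            extract_attention(model, net, F, ("d0", "p0"))


class TestPersistence:
    def test_checkpoint_round_trip_restores_predictions(self, tmp_path):
        net, F, pairs = _train_setup(7)
        cfg = EncoderConfig(hidden_dims=(8, 6, 4), heads=2, epochs=15, seed=4)
        model, _ = train_encoder(net, F, pairs, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = EncoderModel.load(path)
        e1 = encode(net, F, model)
        e2 = encode(net, F, loaded)
        np.testing.assert_array_equal(e1.X_D, e2.X_D)
        np.testing.assert_array_equal(e1.X_P, e2.X_P)
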