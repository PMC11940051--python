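"""GATv2 layer arithmetic, gradients, attention properties, training."""

import numpy as np
import pytest

from lrgat.gat import (
    GATConfig,
    GATv2Network,
    _bce_loss_and_grad,
    gat_aggregate,
    gat_attention,
    gat_score,
    train_link_scorer,
)


# ------------------------------------------------------------- score op

def test_score_zero_attention_vector():
    O = np.eye(2)
    assert gat_score([1.0, 2.0], [3.0, 4.0], O, np.zeros(4)) == 0.0


def test_score_identity_weights_sums_concatenation():
    # O = identity, b = ones, non-negative inputs: LeakyReLU is identity
    O = np.eye(3)
    h_m, h_n = np.array([1.0, 2.0, 3.0]), np.array([4.0, 0.0, 1.0])
    assert gat_score(h_m, h_n, O, np.ones(6)) == pytest.approx(11.0)


def test_score_hand_computed_2d_example():
    O = np.array([[1.0, -1.0], [0.5, 0.0]])
    b = np.array([1.0, 2.0, -1.0, 0.5])
    h_m, h_n = np.array([2.0, 1.0]), np.array([-1.0, 3.0])
    u = np.concatenate([O @ h_m, O @ h_n])  # [1, 1, -4, -0.5]
    g = np.where(u >= 0, u, 0.2 * u)  # [1, 1, -0.8, -0.1]
    expected = float(b @ g)  # 1 + 2 + 0.8 - 0.05
    assert gat_score(h_m, h_n, O, b, slope=0.2) == pytest.approx(expected)
    assert expected == pytest.approx(3.75)


def test_score_dim_mismatch_rejected():
    with pytest.raises(ValueError):
        gat_score([1.0], [1.0, 2.0], np.eye(2), np.ones(4))


# ------------------------------------------------------------ attention

def test_attention_uniform_over_equal_scores():
    assert np.allclose(gat_attention(np.zeros(4)), 0.25)


def test_attention_is_normalised_and_stable():
    alpha = gat_attention(np.array([1000.0, 0.0]))
    assert np.isfinite(alpha).all()
    assert alpha.sum() == pytest.approx(1.0)
    # exact log-sum-exp reference
    ref = np.exp([0.0, -1000.0]) / np.exp([0.0, -1000.0]).sum()
    assert np.allclose(alpha, ref)


def test_attention_empty_neighbourhood_rejected():
    with pytest.raises(ValueError):
        gat_attention(np.array([]))


# ------------------------------------------------------------ aggregation

def test_aggregate_single_neighbour_identity_activation():
    O = np.array([[2.0, 0.0], [0.0, 3.0]])
    h_n = np.array([[1.0, 1.0]])
    out = gat_aggregate(np.array([1.0]), h_n, O, activation=lambda x: x)
    assert np.allclose(out, O @ h_n[0])


def test_aggregate_invariant_to_neighbour_order():
    rng = np.random.default_rng(0)
    O = rng.normal(size=(3, 4))
    feats = rng.normal(size=(5, 4))
    alpha = gat_attention(rng.normal(size=5))
    out = gat_aggregate(alpha, feats, O)
    perm = rng.permutation(5)
    assert np.allclose(out, gat_aggregate(alpha[perm], feats[perm], O))


def test_aggregate_matches_naive_loop():
    rng = np.random.default_rng(1)
    O = rng.normal(size=(2, 3))
    feats = rng.normal(size=(5, 3))
    alpha = gat_attention(rng.normal(size=5))
    naive = np.zeros(2)
    for a, h in zip(alpha, feats):
        naive += a * (O @ h)
    naive = np.where(naive > 0, naive, np.expm1(naive))
    assert np.allclose(gat_aggregate(alpha, feats, O), naive)


# ------------------------------------------------------- network-level

def _tiny_instance(seed=0, n=6, d=4):
    rng = np.random.default_rng(seed)
    H = rng.normal(size=(n, d))
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 3)]
    return H, edges


def test_layer_attention_rows_sum_to_one_every_layer():
    H, edges = _tiny_instance()
    cfg = GATConfig(feature_dim=4, hidden_dim=5, out_dim=2, seed=1)
    net = GATv2Network(cfg)
    dst, src = GATv2Network.with_self_loops(H.shape[0], edges)
    net.forward(H, dst, src)
    for layer in net.layers:
        d, alpha = layer.attention_weights()
        sums = np.zeros(H.shape[0])
        np.add.at(sums, d, alpha)
        assert np.allclose(sums[np.unique(d)], 1.0, atol=1e-6)


def test_network_forward_is_permutation_equivariant():
    H, edges = _tiny_instance(seed=2)
    cfg = GATConfig(feature_dim=4, hidden_dim=5, out_dim=2, seed=3)
    net = GATv2Network(cfg)
    dst, src = GATv2Network.with_self_loops(H.shape[0], edges)
    out = net.forward(H, dst, src)
    perm = np.random.default_rng(4).permutation(H.shape[0])
    inv = np.argsort(perm)
    # relabel: node i -> position inv[i]
    H_p = H[perm]
    edges_p = [(inv[i], inv[j]) for i, j in edges]
    dst_p, src_p = GATv2Network.with_self_loops(H.shape[0], edges_p)
    out_p = net.forward(H_p, dst_p, src_p)
    assert np.allclose(out_p, out[perm], atol=1e-10)


def test_analytic_gradients_match_numerical():
    """Central-difference check of the full backward pass (attention,
    aggregation, residuals, input skip) on a tiny instance."""
    H, edges = _tiny_instance(seed=5)
    cfg = GATConfig(feature_dim=4, hidden_dim=3, out_dim=2, seed=6)
    net = GATv2Network(cfg)
    dst, src = GATv2Network.with_self_loops(H.shape[0], edges)
    pairs = np.array([(0, 1), (2, 3), (4, 5)])
    labels = np.array([1.0, 0.0, 1.0])

    def loss_fn():
        emb = net.forward(H, dst, src)
        loss, _ = _bce_loss_and_grad(emb, pairs, labels)
        return loss

    emb = net.forward(H, dst, src)
    _, dEmb = _bce_loss_and_grad(emb, pairs, labels)
    grads = [g for lg in net.backward(dEmb) for g in lg]
    params = net.parameters()
    eps = 1e-6
    rng = np.random.default_rng(7)
    for p, g in zip(params, grads):
        flat = p.ravel()
        for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            up = loss_fn()
            flat[idx] = old - eps
            down = loss_fn()
            flat[idx] = old
            numeric = (up - down) / (2 * eps)
            assert g.ravel()[idx] == pytest.approx(numeric, abs=1e-6, rel=1e-4)


def test_training_frozen_lr_returns_initial_embeddings():
    H, edges = _tiny_instance(seed=8)
    cfg = GATConfig(feature_dim=4, learning_rate=0.0, epochs=50, seed=9)
    res = train_link_scorer(H, edges, [(0, 1)], [(2, 3)], cfg)
    ref = GATv2Network(cfg)
    dst, src = GATv2Network.with_self_loops(H.shape[0], edges)
    assert np.array_equal(res.embeddings, ref.forward(H, dst, src))


def test_initial_loss_near_log2_with_balanced_labels():
    H, edges = _tiny_instance(seed=10)
    cfg = GATConfig(feature_dim=4, epochs=1, seed=11)
    res = train_link_scorer(H, edges, [(0, 1), (2, 4)], [(2, 3), (1, 5)], cfg)
    assert res.loss_history[0] == pytest.approx(np.log(2), abs=0.1)


def test_training_is_bitwise_deterministic():
    H, edges = _tiny_instance(seed=12)
    cfg = GATConfig(feature_dim=4, epochs=30, seed=13)
    a = train_link_scorer(H, edges, [(0, 1)], [(2, 3)], cfg)
    b = train_link_scorer(H, edges, [(0, 1)], [(2, 3)], cfg)
    assert np.array_equal(a.embeddings, b.embeddings)
    assert np.array_equal(a.loss_history, b.loss_history)


def test_training_reduces_loss_on_learnable_instance():
    H, edges = _tiny_instance(seed=14)
    cfg = GATConfig(feature_dim=4, epochs=100, seed=15)
    res = train_link_scorer(H, edges, [(0, 1), (1, 2)], [(3, 5), (0, 4)], cfg)
    assert res.loss_history[-1] < res.loss_history[0]


def test_training_requires_positive_pairs():
    H, edges = _tiny_instance()
    with pytest.raises(ValueError):
        train_link_scorer(H, edges, [], [(0, 1)], GATConfig(feature_dim=4))
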