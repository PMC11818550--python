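"""Heterogeneous-graph assembly, dynamic thresholding, and propagation."""

import numpy as np
import pytest

from dynheter.autodiff import Tensor
from dynheter.data_io import AffinityTable
from dynheter.hetero_graph import (HeteroGraph, assemble_adjacency, binarize,
                                   build_affinity_block, dynamic_threshold,
                                   feature_matrix, gcn_propagate)


def make_hg(rng, dr=2, dp=3, w1=0.1, w2=0.1):
    Sd = rng.random((dr, dr))
    Sd = (Sd + Sd.T) / 2
    np.fill_diagonal(Sd, 1.0)
    Sp = rng.random((dp, dp))
    Sp = (Sp + Sp.T) / 2
    np.fill_diagonal(Sp, 1.0)
    B = rng.random((dr, dp))
    return HeteroGraph(Sd, Sp, B, [f"d{i}" for i in range(dr)],
                       [f"p{i}" for i in range(dp)],
                       w1=Tensor(w1, requires_grad=True),
                       w2=Tensor(w2, requires_grad=True))


def test_assemble_block_placement():
    Sd, Sp = np.eye(2), np.eye(3)
    B = np.arange(6.0).reshape(2, 3)
    A = assemble_adjacency(Sd, B, Sp).data
    assert A.shape == (5, 5)
    assert np.array_equal(A[:2, 2:], B)
    assert np.array_equal(A[2:, :2], B.T)
    A0 = assemble_adjacency(Sd, np.zeros((2, 3)), Sp).data
    assert np.count_nonzero(A0[:2, 2:]) == 0   # block-diagonal when B = 0


def test_assemble_symmetry_and_shape_errors():
    rng = np.random.default_rng(0)
    Sd = rng.random((4, 4)); Sd = (Sd + Sd.T) / 2
    Sp = rng.random((3, 3)); Sp = (Sp + Sp.T) / 2
    A = assemble_adjacency(Sd, rng.random((4, 3)), Sp).data
    assert np.allclose(A, A.T)
    with pytest.raises(ValueError):
        assemble_adjacency(Sd, rng.random((3, 4)), Sp)


def test_dynamic_threshold_relu_arithmetic():
    hg = make_hg(np.random.default_rng(1), w1=0.1, w2=0.2)
    hg.Sd[0, 1] = hg.Sd[1, 0] = 0.3
    phi = dynamic_threshold(hg).data
    assert phi[0, 1] == pytest.approx(0.2)            # ReLU(0.3 - 0.1)
    hg.Sd[0, 1] = hg.Sd[1, 0] = 0.05
    assert dynamic_threshold(hg).data[0, 1] == 0.0    # clipped
    # B block passes through unchanged
    assert np.array_equal(phi[:2, 2:], hg.B)


def test_threshold_zero_is_identity_and_monotone_sparsifying():
    rng = np.random.default_rng(2)
    hg = make_hg(rng, dr=5, dp=6, w1=0.0, w2=0.0)
    full = assemble_adjacency(hg.Sd, hg.B, hg.Sp).data
    assert np.allclose(dynamic_threshold(hg).data, full)
    counts = []
    for w in np.linspace(0, 1.2, 13):
        hg.w1.data = np.asarray(w)
        counts.append(np.count_nonzero(dynamic_threshold(hg).data[:5, :5]))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_binarize_indicator():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(6, 6)) * (rng.random((6, 6)) > 0.5)
    b = binarize(Tensor(x)).data
    assert np.array_equal(b, (x != 0).astype(float))
    assert np.count_nonzero(binarize(np.zeros((3, 3))).data) == 0


def test_feature_matrix_layout():
    rng = np.random.default_rng(4)
    hg = make_hg(rng, dr=2, dp=3)
    phi1 = binarize(dynamic_threshold(hg))
    psi = feature_matrix(hg, phi1).data
    assert psi.shape == (5, 7)                       # (dr+dp) x (2 + dr + dp)
    assert np.allclose(psi[:, :2].sum(axis=1), 1.0)  # one-hot rows
    assert np.array_equal(psi[:2, 0], [1, 1]) and np.array_equal(psi[2:, 1], [1, 1, 1])
    assert np.array_equal(psi[:, 2:], phi1.data)


def test_gcn_identity_limit():
    H = np.abs(np.random.default_rng(5).normal(size=(4, 3)))
    out = gcn_propagate(Tensor(H), Tensor(np.zeros((4, 4))), Tensor(np.eye(3)))
    assert np.allclose(out.data, H)   # degree-1 self-loops, ReLU of nonneg


def test_gcn_two_node_hand_computation():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    H = np.array([[1.0], [3.0]])
    out = gcn_propagate(Tensor(H), Tensor(A), Tensor(np.eye(1)))
    assert np.allclose(out.data, [[2.0], [2.0]])   # 0.5*1 + 0.5*3 each


def test_gcn_matches_dense_oracle():
    rng = np.random.default_rng(6)
    for _ in range(25):
        n, f, f2 = rng.integers(5, 11), 4, 3
        A = rng.random((n, n)) * (rng.random((n, n)) > 0.5)
        A = (A + A.T) / 2
        H = rng.normal(size=(n, f))
        W = rng.normal(size=(f, f2))
        got = gcn_propagate(Tensor(H), Tensor(A), Tensor(W)).data
        A_hat = A + np.eye(n)
        d = np.diag(1.0 / np.sqrt(A_hat.sum(axis=1)))
        expected = np.maximum(d @ A_hat @ d @ H @ W, 0)
        assert np.allclose(got, expected, atol=1e-6)


def test_gcn_rejects_nan():
    with pytest.raises(ValueError):
        gcn_propagate(Tensor(np.ones((2, 2))), Tensor(np.full((2, 2), np.nan)),
                      Tensor(np.eye(2)))


def test_threshold_gradients_match_finite_differences():
    """Autodiff gradient of a scalar loss w.r.t. w1, w2 on a 5-node toy graph."""
    rng = np.random.default_rng(7)
    hg = make_hg(rng, dr=2, dp=3, w1=0.07, w2=0.13)
    W = Tensor(rng.normal(size=(7, 4)))

    def loss_value():
        phi = dynamic_threshold(hg)
        psi = feature_matrix(hg, binarize(phi))
        return (gcn_propagate(psi, phi, W) ** 2).sum()

    loss = loss_value()
    loss.backward()
    g_w1, g_w2 = hg.w1.grad.copy(), hg.w2.grad.copy()
    eps = 1e-6
    for tensor, g_auto in ((hg.w1, g_w1), (hg.w2, g_w2)):
        base = tensor.data.copy()
        tensor.data = base + eps
        up = float(loss_value().data)
        tensor.data = base - eps
        dn = float(loss_value().data)
        tensor.data = base
        assert abs(float(g_auto) - (up - dn) / (2 * eps)) < 1e-4


def test_affinity_block_masks_heldout_pairs():
    table = AffinityTable([("d0", "p0", 5.0), ("d0", "p1", 7.0), ("d1", "p0", 6.0)])
    B = build_affinity_block(table, ["d0", "d1"], ["p0", "p1"],
                             train_indices=np.array([0, 2]))
    assert B[0, 1] == 0.0                      # held-out pair stays exactly zero
    assert B[0, 0] == 0.0 and B[1, 0] == 1.0   # min-max over training values
    B_bin = build_affinity_block(table, ["d0", "d1"], ["p0", "p1"], scale="binary")
    assert np.array_equal(B_bin, [[1, 1], [1, 0]])
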