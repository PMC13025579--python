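"""LightGCN propagation, layer aggregation, spatial GCN and the decoder."""

import numpy as np
import pytest
import scipy.sparse as sp

from hetspot import heterograph as hg
from hetspot.encoder import (
    BipartiteOperator,
    EmbeddingState,
    MLPEncoder,
    aggregate_layers,
    decode_edges,
    decode_full,
    encoder_backward,
    encoder_forward,
    lightgcn_propagate,
    spatial_gcn,
    spatial_operator,
)
from hetspot.io import SpatialGraph


def _graph_from_R(R, n_slices=1):
    mats = [sp.csr_matrix(np.asarray(R, dtype=float))] * n_slices
    return hg.assemble_adjacency(mats)


def _dense_sym_norm(C):
    deg = C.sum(1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return dinv[:, None] * C * dinv[None, :]


# ---------------------------------------------------------------------------
# LightGCN


def test_single_edge_swaps_embeddings(rng):
    graph = _graph_from_R([[1.0]])
    op = BipartiteOperator(graph)
    es0 = rng.normal(size=(1, 4))
    eg0 = rng.normal(size=(1, 4))
    state = lightgcn_propagate(EmbeddingState(es0, eg0), op, K=1)
    np.testing.assert_allclose(state.layer_spot[1], eg0)
    np.testing.assert_allclose(state.layer_gene[1], es0)


def test_star_graph_normalization(rng):
    # one gene linked to 4 spots: spot degree 1, gene degree 4 -> factor 1/2
    R = np.ones((4, 1))
    op = BipartiteOperator(_graph_from_R(R))
    es0 = rng.normal(size=(4, 3))
    eg0 = rng.normal(size=(1, 3))
    state = lightgcn_propagate(EmbeddingState(es0, eg0), op, K=1)
    for i in range(4):
        np.testing.assert_allclose(state.layer_spot[1][i], eg0[0] / 2.0)


def test_propagation_linearity(rng):
    R = (rng.random((6, 5)) < 0.6).astype(float)
    R[R.sum(1) == 0, 0] = 1
    op = BipartiteOperator(_graph_from_R(R))
    es0 = rng.normal(size=(6, 4))
    eg0 = rng.normal(size=(5, 4))
    s1 = lightgcn_propagate(EmbeddingState(es0, eg0), op, K=2)
    s2 = lightgcn_propagate(EmbeddingState(2 * es0, 2 * eg0), op, K=2)
    for k in range(3):
        np.testing.assert_allclose(s2.layer_spot[k], 2 * s1.layer_spot[k], atol=1e-12)
        np.testing.assert_allclose(s2.layer_gene[k], 2 * s1.layer_gene[k], atol=1e-12)


def test_lightgcn_matches_dense_oracle_single_slice(rng):
    """Sparse propagation equals multiplication by the dense symmetric-
    normalized block adjacency, per layer, on a small graph."""
    R = (rng.random((9, 7)) < 0.5).astype(float)
    R[R.sum(1) == 0, 0] = 1
    graph = _graph_from_R(R)
    op = BipartiteOperator(graph)
    Chat = _dense_sym_norm(hg.dense_block_adjacency(graph, 0))
    es0 = rng.normal(size=(9, 5))
    eg0 = rng.normal(size=(7, 5))
    state = lightgcn_propagate(EmbeddingState(es0, eg0), op, K=3)
    e = np.vstack([es0, eg0])
    for k in range(1, 4):
        e = Chat @ e
        np.testing.assert_allclose(state.layer_spot[k], e[:9], atol=1e-10)
        np.testing.assert_allclose(state.layer_gene[k], e[9:], atol=1e-10)


def test_lightgcn_dense_oracle_multi_slice(rng):
    """Two slices: pooled gene degrees plus the 1/B prefactor on the gene
    update, against an explicitly built dense operator."""
    B = 2
    Rs = []
    for _ in range(B):
        R = (rng.random((5, 6)) < 0.6).astype(float)
        R[R.sum(1) == 0, 0] = 1
        Rs.append(R)
    graph = hg.assemble_adjacency([sp.csr_matrix(R) for R in Rs])
    op = BipartiteOperator(graph)
    Rstack = np.vstack(Rs)
    ds = Rstack.sum(1)
    dg = Rstack.sum(0)
    Rhat = Rstack / np.sqrt(ds[:, None] * dg[None, :])
    es0 = rng.normal(size=(10, 3))
    eg0 = rng.normal(size=(6, 3))
    state = lightgcn_propagate(EmbeddingState(es0, eg0), op, K=2)
    s_prev, g_prev = es0, eg0
    for k in range(1, 3):
        s_new = Rhat @ g_prev
        g_new = (1.0 / B) * Rhat.T @ s_prev
        np.testing.assert_allclose(state.layer_spot[k], s_new, atol=1e-10)
        np.testing.assert_allclose(state.layer_gene[k], g_new, atol=1e-10)
        s_prev, g_prev = s_new, g_new


def test_permutation_equivariance(rng):
    R = (rng.random((8, 6)) < 0.5).astype(float)
    R[R.sum(1) == 0, 0] = 1
    perm = rng.permutation(8)
    op1 = BipartiteOperator(_graph_from_R(R))
    op2 = BipartiteOperator(_graph_from_R(R[perm]))
    es0 = rng.normal(size=(8, 4))
    eg0 = rng.normal(size=(6, 4))
    s1 = lightgcn_propagate(EmbeddingState(es0, eg0), op1, K=2)
    s2 = lightgcn_propagate(EmbeddingState(es0[perm], eg0), op2, K=2)
    for k in range(3):
        np.testing.assert_allclose(s2.layer_spot[k], s1.layer_spot[k][perm], atol=1e-12)
        np.testing.assert_allclose(s2.layer_gene[k], s1.layer_gene[k], atol=1e-12)


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_k0_identity(rng):
    es0, eg0 = rng.normal(size=(3, 2)), rng.normal(size=(2, 2))
    state = EmbeddingState(es0, eg0)
    state.layer_spot, state.layer_gene = [es0], [eg0]
    aggregate_layers(state)
    np.testing.assert_allclose(state.prelim_spot, es0)


def test_aggregate_uniform_thirds(rng):
    R = (rng.random((5, 4)) < 0.7).astype(float)
    R[R.sum(1) == 0, 0] = 1
    op = BipartiteOperator(_graph_from_R(R))
    es0, eg0 = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
    state = lightgcn_propagate(EmbeddingState(es0, eg0), op, K=2)
    aggregate_layers(state)
    np.testing.assert_allclose(state.layer_weights, [1 / 3] * 3)
    manual = (state.layer_spot[0] + state.layer_spot[1] + state.layer_spot[2]) / 3
    np.testing.assert_allclose(state.prelim_spot, manual, atol=1e-12)


def test_aggregate_identical_layers_convexity(rng):
    v = rng.normal(size=(4, 2))
    state = EmbeddingState(v, v.copy())
    state.layer_spot = [v, v, v]
    state.layer_gene = [v, v, v]
    aggregate_layers(state)
    np.testing.assert_allclose(state.prelim_spot, v, atol=1e-12)


def test_aggregate_weight_length_mismatch(rng):
    state = EmbeddingState(rng.normal(size=(2, 2)), rng.normal(size=(2, 2)))
    state.layer_spot = [state.init_spot] * 3
    state.layer_gene = [state.init_gene] * 3
    with pytest.raises(ValueError):
        aggregate_layers(state, weights=[0.5, 0.5])


# ---------------------------------------------------------------------------
# spatial GCN


def _path_graph(n):
    nbrs = []
    for i in range(n):
        s = [j for j in (i - 1, i + 1) if 0 <= j < n]
        nbrs.append(np.array(s))
    return SpatialGraph(slice_id="p", neighbor_sets=nbrs)


def test_path_graph_neighbor_means():
    A = spatial_operator([_path_graph(3)])
    z = np.array([[0.0], [3.0], [6.0]])
    out = spatial_gcn(z, A, layers=1)
    np.testing.assert_allclose(out, [[3.0], [3.0], [3.0]])


def test_constant_embedding_fixed_point(rng):
    A = spatial_operator([_path_graph(6)])
    v = rng.normal(size=(1, 4))
    z = np.repeat(v, 6, axis=0)
    np.testing.assert_allclose(spatial_gcn(z, A, layers=2), z, atol=1e-12)


def test_single_neighbor_copies(rng):
    g = SpatialGraph(slice_id="s", neighbor_sets=[np.array([1]), np.array([0])])
    A = spatial_operator([g])
    z = rng.normal(size=(2, 3))
    out = spatial_gcn(z, A, layers=1)
    np.testing.assert_allclose(out[0], z[1])
    np.testing.assert_allclose(out[1], z[0])


def test_isolated_spot_keeps_value(rng):
    g = SpatialGraph(
        slice_id="s",
        neighbor_sets=[np.array([1]), np.array([0]), np.array([], dtype=int)],
    )
    A = spatial_operator([g])
    z = rng.normal(size=(3, 2))
    out = spatial_gcn(z, A, layers=2)
    np.testing.assert_allclose(out[2], z[2])


# ---------------------------------------------------------------------------
# decoder


def test_decode_values(rng):
    z = np.zeros((2, 3))
    full = decode_full(z, np.zeros((4, 3)))
    np.testing.assert_allclose(full, 0.5)
    # dot product log(3) -> sigmoid 0.75
    zs = np.array([[np.log(3.0), 0.0]])
    zg = np.array([[1.0, 0.0]])
    np.testing.assert_allclose(decode_full(zs, zg)[0, 0], 0.75, rtol=1e-12)
    # saturation
    big = np.array([[50.0]])
    assert decode_full(big, np.array([[1.0]]))[0, 0] > 1 - 1e-12
    # edge-wise equals full
    zs = rng.normal(size=(5, 4))
    zg = rng.normal(size=(6, 4))
    edges = np.array([[0, 0], [4, 5], [2, 3]])
    np.testing.assert_allclose(
        decode_edges(zs, zg, edges), decode_full(zs, zg)[edges[:, 0], edges[:, 1]]
    )


def test_decoder_range(rng):
    zs = rng.normal(scale=2.0, size=(10, 6))
    zg = rng.normal(scale=2.0, size=(8, 6))
    X = decode_full(zs, zg)
    assert (X > 0).all() and (X < 1).all()


# ---------------------------------------------------------------------------
# full encoder linearity + adjoint


def test_encoder_superposition(tiny_graphs, rng):
    graph, A, _ = tiny_graphs
    n, G = graph.n_total_spots, graph.n_genes
    op = BipartiteOperator(graph)
    e1 = (rng.normal(size=(n, 4)), rng.normal(size=(G, 4)))
    e2 = (rng.normal(size=(n, 4)), rng.normal(size=(G, 4)))
    zs1, zg1 = encoder_forward(*e1, op, A)
    zs2, zg2 = encoder_forward(*e2, op, A)
    zs, zg = encoder_forward(e1[0] + e2[0], e1[1] + e2[1], op, A)
    np.testing.assert_allclose(zs, zs1 + zs2, atol=1e-10)
    np.testing.assert_allclose(zg, zg1 + zg2, atol=1e-10)


def test_encoder_adjoint_identity(tiny_graphs, rng):
    """<F(x), y> == <x, F*(y)> for the linear encoder and its backward."""
    graph, A, _ = tiny_graphs
    n, G = graph.n_total_spots, graph.n_genes
    op = BipartiteOperator(graph)
    xs, xg = rng.normal(size=(n, 3)), rng.normal(size=(G, 3))
    ys, yg = rng.normal(size=(n, 3)), rng.normal(size=(G, 3))
    zs, zg = encoder_forward(xs, xg, op, A)
    gs, gg = encoder_backward(ys, yg, op, A)
    lhs = np.sum(zs * ys) + np.sum(zg * yg)
    rhs = np.sum(xs * gs) + np.sum(xg * gg)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-10)


# ---------------------------------------------------------------------------
# MLP ablation encoder


def test_mlp_shape_determinism_and_bias_only(rng):
    X = rng.normal(size=(7, 12))
    m1 = MLPEncoder(12, depth=2, width=5, seed=3)
    m2 = MLPEncoder(12, depth=2, width=5, seed=3)
    np.testing.assert_array_equal(m1(X), m2(X))
    assert m1(X).shape == (7, 5)
    # zero weights -> constant (bias-only) output
    m1.weights = [np.zeros_like(W) for W in m1.weights]
    out = m1(X)
    np.testing.assert_allclose(out, np.repeat(out[:1], 7, axis=0))


def test_mlp_backward_matches_finite_difference(rng):
    X = rng.normal(size=(6, 8))
    mlp = MLPEncoder(8, depth=2, width=4, seed=0)
    # move the biases off zero so no ReLU pre-activation sits exactly at its
    # kink (zero-bias init + a fully inactive row makes the hinge ambiguous)
    mlp.biases = [rng.normal(scale=0.3, size=b.shape) for b in mlp.biases]
    d_out = rng.normal(size=(6, 4))
    out, cache = mlp.forward(X)
    loss = np.sum(out * d_out)
    dWs, dbs = mlp.backward(d_out, cache)
    h = 1e-6
    for arr, grad in [(mlp.weights[0], dWs[0]), (mlp.biases[1], dbs[1])]:
        idx = tuple(rng.integers(0, s) for s in arr.shape)
        arr[idx] += h
        lp = np.sum(mlp(X) * d_out)
        arr[idx] -= 2 * h
        lm = np.sum(mlp(X) * d_out)
        arr[idx] += h
        np.testing.assert_allclose((lp - lm) / (2 * h), grad[idx], rtol=1e-4)
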