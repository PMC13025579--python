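"""Dual-stage encoder: LightGCN over the spot-gene graph, then a spatial GCN.

Stage one is weight-free collaborative-filtering message passing on the
bipartite spot-gene graph: each layer replaces a spot embedding by the
symmetric-degree-normalized sum of its genes' embeddings (and vice versa),
and the K+1 layer outputs are combined by a weighted sum (uniform weights by
default) to curb over-smoothing.  Stage two refines the spot embeddings by
``v`` rounds of plain neighbour averaging on the spatial k-NN graph.  A dot
product decoder with a sigmoid maps spot/gene embedding pairs back to edge
scores in (0, 1).

The whole encoder is a linear map of the initial embeddings (the decoder
excepted), so its adjoint is exact and cheap; ``encoder_backward`` implements
it for the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .heterograph import HeteroGraph
from .io import SpatialGraph


def _inv_sqrt(deg: np.ndarray) -> np.ndarray:
    out = np.zeros_like(deg, dtype=float)
    nz = deg > 0
    out[nz] = 1.0 / np.sqrt(deg[nz])
    return out


class BipartiteOperator:
    """Normalized spot<->gene propagation operator of the combined graph.

    Holds ``Rhat = D_s^{-1/2} R D_g^{-1/2}`` with slices stacked along spots
    and gene degrees pooled over slices.  The gene update carries an extra
    1/B slice-average prefactor (toggled by ``gene_slice_average``, on by
    default); the spot update is ``Rhat @ E_g``.
    """

    def __init__(self, graph: HeteroGraph, gene_slice_average: bool = True):
        R = sp.vstack([Ri for Ri in graph.incidence], format="csr")
        d_spot = np.concatenate(graph.spot_degrees)
        d_gene = graph.gene_degrees
        Ds = sp.diags(_inv_sqrt(d_spot))
        Dg = sp.diags(_inv_sqrt(d_gene))
        self.rhat = (Ds @ R @ Dg).tocsr()
        self.rhat_T = self.rhat.T.tocsr()
        self.n_slices = graph.n_slices
        self.gene_prefactor = 1.0 / graph.n_slices if gene_slice_average else 1.0

    def spot_update(self, e_gene: np.ndarray) -> np.ndarray:
        return self.rhat @ e_gene

    def gene_update(self, e_spot: np.ndarray) -> np.ndarray:
        return self.gene_prefactor * (self.rhat_T @ e_spot)

    # adjoints (Rhat is real, so transposes)
    def spot_update_adj(self, d_spot: np.ndarray) -> np.ndarray:
        return self.rhat_T @ d_spot

    def gene_update_adj(self, d_gene: np.ndarray) -> np.ndarray:
        return self.gene_prefactor * (self.rhat @ d_gene)


def spatial_operator(
    graphs: list[SpatialGraph], self_loop: bool = False
) -> sp.csr_matrix:
    """Block-diagonal neighbour-mean matrix over all slices' spots.

    Row i averages spot i's spatial neighbours (optionally including i
    itself); an isolated spot keeps its previous value (identity row).
    """
    blocks = []
    for g in graphs:
        n = g.n_spots
        rows, cols, vals = [], [], []
        for i, nbrs in enumerate(g.neighbor_sets):
            members = list(nbrs) + ([i] if self_loop else [])
            if not members:
                members = [i]  # isolated: carry value forward
            w = 1.0 / len(members)
            for j in members:
                rows.append(i)
                cols.append(int(j))
                vals.append(w)
        blocks.append(sp.csr_matrix((vals, (rows, cols)), shape=(n, n)))
    return sp.block_diag(blocks, format="csr")


@dataclass
class EmbeddingState:
    """Initial, layer-wise and final embeddings of one encoder pass."""

    init_spot: np.ndarray  # (N_total, d_emb), learnable
    init_gene: np.ndarray  # (G, d_emb), learnable
    layer_spot: list[np.ndarray] = field(default_factory=list)
    layer_gene: list[np.ndarray] = field(default_factory=list)
    layer_weights: np.ndarray | None = None
    prelim_spot: np.ndarray | None = None
    final_spot: np.ndarray | None = None
    final_gene: np.ndarray | None = None


def init_embeddings(
    n_total_spots: int, n_genes: int, d_emb: int = 64, seed: int = 0, std: float = 0.1
) -> EmbeddingState:
    """Seeded scaled-normal initialization of the learnable embeddings."""
    rng = np.random.default_rng(seed)
    return EmbeddingState(
        init_spot=rng.normal(0.0, std, size=(n_total_spots, d_emb)),
        init_gene=rng.normal(0.0, std, size=(n_genes, d_emb)),
    )


def lightgcn_propagate(
    state: EmbeddingState, op: BipartiteOperator, K: int = 2
) -> EmbeddingState:
    """Run K weight-free propagation layers; layer 0 is the initialization.

    Spot layer k is built from gene layer k-1 and gene layer k from spot
    layer k-1 (simultaneous update).  Isolated nodes receive zero messages,
    so only their layer-0 term survives aggregation.
    """
    layers_s = [state.init_spot]
    layers_g = [state.init_gene]
    for _ in range(K):
        layers_s.append(op.spot_update(layers_g[-1]))
        layers_g.append(op.gene_update(layers_s[-2]))
    state.layer_spot = layers_s
    state.layer_gene = layers_g
    return state


def uniform_weights(K: int) -> np.ndarray:
    return np.full(K + 1, 1.0 / (K + 1))


def aggregate_layers(
    state: EmbeddingState, weights: np.ndarray | None = None
) -> EmbeddingState:
    """Weighted sum of the K+1 layers -> preliminary spot / final gene embeddings."""
    K = len(state.layer_spot) - 1
    w = uniform_weights(K) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != K + 1:
        raise ValueError(f"need {K + 1} layer weights, got {len(w)}")
    if ((w < 0) | (w > 1)).any():
        raise ValueError("layer weights must lie in [0, 1]")
    state.layer_weights = w
    state.prelim_spot = sum(wk * ek for wk, ek in zip(w, state.layer_spot))
    state.final_gene = sum(wk * ek for wk, ek in zip(w, state.layer_gene))
    return state


def spatial_gcn(
    prelim_spot: np.ndarray, A: sp.csr_matrix, layers: int = 2
) -> np.ndarray:
    """``layers`` rounds of neighbour-mean aggregation of spot embeddings."""
    z = prelim_spot
    for _ in range(layers):
        z = A @ z
    return z


def decode_edges(
    z_spot: np.ndarray, z_gene: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Sigmoid dot-product scores for the given (spot, gene) index pairs."""
    dots = np.einsum("ij,ij->i", z_spot[edges[:, 0]], z_gene[edges[:, 1]])
    return _sigmoid(dots)


def decode_full(z_spot: np.ndarray, z_gene: np.ndarray) -> np.ndarray:
    """Full reconstructed matrix sigma(Z_s Z_g^T); small inputs only."""
    return _sigmoid(z_spot @ z_gene.T)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# linear encoder forward/adjoint for the trainer


def encoder_forward(
    init_spot: np.ndarray,
    init_gene: np.ndarray,
    op: BipartiteOperator,
    A: sp.csr_matrix,
    K: int = 2,
    gcn_layers: int = 2,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full dual-stage pass: returns (final_spot Z_s, final_gene Z_g)."""
    state = EmbeddingState(init_spot=init_spot, init_gene=init_gene)
    lightgcn_propagate(state, op, K=K)
    aggregate_layers(state, weights)
    z_s = spatial_gcn(state.prelim_spot, A, layers=gcn_layers)
    return z_s, state.final_gene


def encoder_backward(
    d_final_spot: np.ndarray,
    d_final_gene: np.ndarray,
    op: BipartiteOperator,
    A: sp.csr_matrix,
    K: int = 2,
    gcn_layers: int = 2,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint of :func:`encoder_forward` w.r.t. the initial embeddings.

    Exact because every stage is linear: the spatial GCN adjoint applies A^T
    ``gcn_layers`` times, then each LightGCN layer's cotangent is pushed down
    through the transposed propagation while the layer-weight contributions
    are injected at the matching depth.
    """
    w = uniform_weights(K) if weights is None else np.asarray(weights, dtype=float)
    d_prelim = d_final_spot
    AT = A.T.tocsr()
    for _ in range(gcn_layers):
        d_prelim = AT @ d_prelim
    gs = w[K] * d_prelim
    gg = w[K] * d_final_gene
    for k in range(K, 0, -1):
        new_gs = w[k - 1] * d_prelim + op.gene_update_adj(gg)
        new_gg = w[k - 1] * d_final_gene + op.spot_update_adj(gs)
        gs, gg = new_gs, new_gg
    return gs, gg


# ---------------------------------------------------------------------------
# MLP ablation encoder


class MLPEncoder:
    """Feed-forward replacement for the graph stage (ablation harness only).

    Maps normalized expression straight to preliminary spot embeddings with
    ``depth`` hidden ReLU layers of width ``width`` and a linear output of the
    same width, matching the graph encoder's depth and dimensionality.  The
    spatial GCN and decoder stages are unchanged downstream.
    """

    def __init__(
        self, n_features: int, depth: int = 2, width: int = 64, seed: int = 0
    ):
        rng = np.random.default_rng(seed)
        dims = [n_features] + [width] * depth + [width]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.depth = depth
        self.width = width

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = params[:n]
        self.biases = params[n:]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns the output and the cache of pre-activations for backward."""
        h = np.asarray(X, dtype=float)
        cache = [h]
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            h = np.maximum(z, 0.0) if li < n_layers - 1 else z
            cache.append(h)
        return h, cache

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(
        self, d_out: np.ndarray, cache: list[np.ndarray]
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients (dWs, dbs) given the output cotangent."""
        n_layers = len(self.weights)
        dWs = [None] * n_layers
        dbs = [None] * n_layers
        g = d_out
        for li in range(n_layers - 1, -1, -1):
            h_in = cache[li]
            if li < n_layers - 1:
                g = g * (cache[li + 1] > 0)  # ReLU mask of this layer's output
            dWs[li] = h_in.T @ g
            dbs[li] = g.sum(axis=0)
            g = g @ self.weights[li].T
        return dWs, dbs
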