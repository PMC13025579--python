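"""Self-supervised objective and the Adam training loop.

The objective combines (i) an edge-reconstruction MSE evaluated on a sampled
positive subgraph (10% of observed spot-gene edges per slice) and an equally
sized negative subgraph, (ii) the triplet contrastive loss on the final spot
embeddings, and (iii) a Frobenius regularizer on the initial embeddings:

    L_total = L_MSE + lambda1 * L_CL + lambda2 * L_reg

The only learnable tensors of the default encoder are the initial spot and
gene embeddings; every encoder stage is linear, so gradients are assembled
analytically (decoder sigmoid and hinge handled in closed form) and verified
against finite differences in the test suite.  Optimization uses an Adam
implementation operating on NumPy arrays; a fixed seed makes runs bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .contrastive import TripletSet, triplet_loss_grad
from .encoder import (
    BipartiteOperator,
    EmbeddingState,
    MLPEncoder,
    encoder_backward,
    encoder_forward,
    init_embeddings,
    spatial_gcn,
    _sigmoid,
)
from .heterograph import EdgeSubgraphs, HeteroGraph


@dataclass
class TrainingConfig:
    """All tunable knobs; defaults follow the method's reference settings."""

    K_layers: int = 2
    gcn_layers: int = 2
    d_emb: int = 64
    pca_d: int = 200
    spatial_k: int = 7
    k_knn: int = 20
    k_mnn: int = 5
    louvain_r: float = 1.0
    margin_l: float = 1.0
    edge_fraction: float = 0.10
    lambda1: float = 1.0
    lambda2: float = 1e-3
    learning_rate: float = 1e-3
    epochs: int = 600
    seed: int = 0
    mode: str = "single"
    n_hvg: int = 2000
    init_std: float = 0.1
    self_loop: bool = False
    gene_slice_average: bool = True
    binary_targets: bool = False
    resample_edges_per_epoch: bool = False
    ablate: str | None = None  # None | "mlp" | "no-cl"

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1/lambda2 must be >= 0")
        if not (0 < self.edge_fraction <= 1):
            raise ValueError("edge_fraction must be in (0, 1]")
        if self.mode not in {"single", "multi"}:
            raise ValueError("mode must be 'single' or 'multi'")


@dataclass
class TrainLog:
    """Per-epoch loss records plus the config snapshot."""

    mse: list[float] = field(default_factory=list)
    cl: list[float] = field(default_factory=list)
    reg: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def record(self, mse: float, cl: float, reg: float, total: float) -> None:
        self.mse.append(mse)
        self.cl.append(cl)
        self.reg.append(reg)
        self.total.append(total)


# ---------------------------------------------------------------------------
# loss pieces


def edge_targets(
    norm_exprs: list[np.ndarray], subgraphs: EdgeSubgraphs, binary: bool = False
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-slice regression targets for the sampled positive/negative edges.

    The sigmoid decoder lives in (0,1) while log-normalized expression is
    unbounded, so positive-edge targets are the normalized values scaled by
    the slice maximum into [0,1]; negative edges (unexpressed pairs) target
    exactly 0.  ``binary=True`` regresses the 0/1 incidence instead.
    """
    pos_t, neg_t = [], []
    for X, pos, neg in zip(norm_exprs, subgraphs.positive_edges, subgraphs.negative_edges):
        if binary:
            pos_t.append(np.ones(len(pos)))
        else:
            mx = X.max()
            pos_t.append(X[pos[:, 0], pos[:, 1]] / (mx if mx > 0 else 1.0))
        neg_t.append(np.zeros(len(neg)))
    return pos_t, neg_t


def mse_loss(
    z_spot_slices: list[np.ndarray],
    z_gene: np.ndarray,
    subgraphs: EdgeSubgraphs,
    pos_targets: list[np.ndarray],
    neg_targets: list[np.ndarray],
) -> float:
    """Summed per-slice edge-reconstruction MSE (positive + negative terms)."""
    total = 0.0
    for zs, pos, neg, tp, tn in zip(
        z_spot_slices,
        subgraphs.positive_edges,
        subgraphs.negative_edges,
        pos_targets,
        neg_targets,
    ):
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("empty edge subgraph")
        xp = _sigmoid(np.einsum("ij,ij->i", zs[pos[:, 0]], z_gene[pos[:, 1]]))
        xn = _sigmoid(np.einsum("ij,ij->i", zs[neg[:, 0]], z_gene[neg[:, 1]]))
        total += float(((tp - xp) ** 2).mean() + ((tn - xn) ** 2).mean())
    return total


def mse_loss_grad(
    z_spot: np.ndarray,
    z_gene: np.ndarray,
    subgraphs: EdgeSubgraphs,
    pos_targets: list[np.ndarray],
    neg_targets: list[np.ndarray],
    offsets: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """MSE and its gradients w.r.t. final spot and gene embeddings.

    The edge sets are fixed during training, so the scatter of per-edge
    contributions onto spot/gene rows is precomputed as sparse matrices and
    cached on the subgraph object.
    """
    from .contrastive import _scatter_matrix

    cache = getattr(subgraphs, "_scatter_cache", None)
    if cache is None:
        cache = []
        for b, (pos, neg) in enumerate(
            zip(subgraphs.positive_edges, subgraphs.negative_edges)
        ):
            off = int(offsets[b])
            entry = []
            for edges in (pos, neg):
                si = edges[:, 0] + off
                gj = edges[:, 1]
                entry.append(
                    (
                        si,
                        gj,
                        _scatter_matrix(si, z_spot.shape[0]),
                        _scatter_matrix(gj, z_gene.shape[0]),
                    )
                )
            cache.append(entry)
        subgraphs._scatter_cache = cache  # type: ignore[attr-defined]
    loss = 0.0
    d_spot = np.zeros_like(z_spot)
    d_gene = np.zeros_like(z_gene)
    for b, (tp, tn) in enumerate(zip(pos_targets, neg_targets)):
        for (si, gj, Ss, Sg), targets in zip(cache[b], (tp, tn)):
            zs = z_spot[si]
            zg = z_gene[gj]
            xhat = _sigmoid(np.einsum("ij,ij->i", zs, zg))
            resid = xhat - targets
            loss += float((resid**2).mean())
            coef = (2.0 / len(si)) * resid * xhat * (1.0 - xhat)
            d_spot += Ss @ (coef[:, None] * zg)
            d_gene += Sg @ (coef[:, None] * zs)
    return loss, d_spot, d_gene


def reg_loss(init_spot: np.ndarray, init_gene: np.ndarray) -> float:
    """Frobenius regularizer (||E_s0||_F^2 + ||E_g0||_F^2) / (2 (N_total + G))."""
    n_total = init_spot.shape[0]
    G = init_gene.shape[0]
    return float(
        (np.sum(init_spot**2) + np.sum(init_gene**2)) / (2.0 * (n_total + G))
    )


def total_loss(l_mse: float, l_cl: float, l_reg: float, lambda1: float, lambda2: float) -> float:
    return l_mse + lambda1 * l_cl + lambda2 * l_reg


# ---------------------------------------------------------------------------
# Adam


class Adam:
    """Standard Adam over a list of NumPy parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop


def _split_rows(z: np.ndarray, offsets: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    return [z[int(o) : int(o) + n] for o, n in zip(offsets, sizes)]


def compute_losses_and_grads(
    init_spot: np.ndarray,
    init_gene: np.ndarray,
    op: BipartiteOperator,
    A: sp.csr_matrix,
    subgraphs: EdgeSubgraphs,
    pos_targets: list[np.ndarray],
    neg_targets: list[np.ndarray],
    triplets: TripletSet | None,
    offsets: np.ndarray,
    cfg: TrainingConfig,
) -> tuple[dict, np.ndarray, np.ndarray]:
    """One forward/backward pass; returns loss dict and init-embedding grads."""
    z_spot, z_gene = encoder_forward(
        init_spot, init_gene, op, A, K=cfg.K_layers, gcn_layers=cfg.gcn_layers
    )
    l_mse, d_zs, d_zg = mse_loss_grad(
        z_spot, z_gene, subgraphs, pos_targets, neg_targets, offsets
    )
    if triplets is not None and cfg.lambda1 > 0:
        l_cl, d_zs_cl = triplet_loss_grad(z_spot, triplets, margin=cfg.margin_l)
        d_zs = d_zs + cfg.lambda1 * d_zs_cl
    else:
        l_cl = 0.0
    d_init_s, d_init_g = encoder_backward(
        d_zs, d_zg, op, A, K=cfg.K_layers, gcn_layers=cfg.gcn_layers
    )
    l_reg = reg_loss(init_spot, init_gene)
    denom = init_spot.shape[0] + init_gene.shape[0]
    d_init_s = d_init_s + cfg.lambda2 * init_spot / denom
    d_init_g = d_init_g + cfg.lambda2 * init_gene / denom
    losses = {
        "mse": l_mse,
        "cl": l_cl,
        "reg": l_reg,
        "total": total_loss(l_mse, l_cl, l_reg, cfg.lambda1, cfg.lambda2),
    }
    return losses, d_init_s, d_init_g


def train(
    graph: HeteroGraph,
    A: sp.csr_matrix,
    subgraphs: EdgeSubgraphs,
    norm_exprs: list[np.ndarray],
    triplets: TripletSet | None,
    cfg: TrainingConfig,
) -> tuple[EmbeddingState, TrainLog]:
    """Optimize the initial embeddings with Adam; returns final state and log.

    ``epochs=0`` returns the propagated random initialization unchanged.
    Aborts with a diagnostic if any loss component turns non-finite.  With
    ``resample_edges_per_epoch`` the reconstruction edge sets are redrawn
    every epoch (seeded per epoch) instead of staying fixed; the default
    static sample keeps the loss surface stable.
    """
    offsets = np.concatenate([[0], np.cumsum(graph.n_spots)[:-1]]).astype(int)
    state = init_embeddings(
        graph.n_total_spots, graph.n_genes, d_emb=cfg.d_emb,
        seed=cfg.seed, std=cfg.init_std,
    )
    pos_t, neg_t = edge_targets(norm_exprs, subgraphs, binary=cfg.binary_targets)
    op = BipartiteOperator(graph, gene_slice_average=cfg.gene_slice_average)
    log = TrainLog(seed=cfg.seed, config=asdict(cfg))
    opt = Adam([state.init_spot, state.init_gene], lr=cfg.learning_rate)
    for epoch in range(cfg.epochs):
        if cfg.resample_edges_per_epoch and epoch > 0:
            from .heterograph import sample_edge_subgraphs

            subgraphs = sample_edge_subgraphs(
                graph, fraction=cfg.edge_fraction,
                seed=(cfg.seed + 1 + epoch) % (2**31),
            )
            pos_t, neg_t = edge_targets(
                norm_exprs, subgraphs, binary=cfg.binary_targets
            )
        losses, gs, gg = compute_losses_and_grads(
            state.init_spot, state.init_gene, op, A, subgraphs,
            pos_t, neg_t, triplets, offsets, cfg,
        )
        for name, val in losses.items():
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss component {name!r} at epoch {epoch}"
                )
        log.record(losses["mse"], losses["cl"], losses["reg"], losses["total"])
        opt.step([gs, gg])
    # final forward pass with the trained embeddings
    z_spot, z_gene = encoder_forward(
        state.init_spot, state.init_gene, op, A,
        K=cfg.K_layers, gcn_layers=cfg.gcn_layers,
    )
    state.final_spot = z_spot
    state.final_gene = z_gene
    return state, log


def train_mlp_variant(
    graph: HeteroGraph,
    A: sp.csr_matrix,
    subgraphs: EdgeSubgraphs,
    norm_exprs: list[np.ndarray],
    triplets: TripletSet | None,
    cfg: TrainingConfig,
) -> tuple[EmbeddingState, TrainLog]:
    """Ablation: the graph stage is replaced by an MLP on normalized expression.

    Spot embeddings come from a feed-forward network of matching depth and
    width; gene embeddings stay free learnable vectors.  The spatial GCN,
    decoder and losses are unchanged; the regularizer covers the gene
    embeddings and the MLP weight matrices with the same scaling.
    """
    X = np.vstack(norm_exprs)
    offsets = np.concatenate([[0], np.cumsum(graph.n_spots)[:-1]]).astype(int)
    rng = np.random.default_rng(cfg.seed)
    mlp = MLPEncoder(X.shape[1], depth=cfg.K_layers, width=cfg.d_emb, seed=cfg.seed)
    e_gene = rng.normal(0.0, cfg.init_std, size=(graph.n_genes, cfg.d_emb))
    pos_t, neg_t = edge_targets(norm_exprs, subgraphs, binary=cfg.binary_targets)
    denom = graph.n_total_spots + graph.n_genes
    params = mlp.params + [e_gene]
    opt = Adam(params, lr=cfg.learning_rate)
    log = TrainLog(seed=cfg.seed, config=asdict(cfg))
    AT = A.T.tocsr()
    for epoch in range(cfg.epochs):
        prelim, cache = mlp.forward(X)
        z_spot = spatial_gcn(prelim, A, layers=cfg.gcn_layers)
        l_mse, d_zs, d_zg = mse_loss_grad(
            z_spot, e_gene, subgraphs, pos_t, neg_t, offsets
        )
        if triplets is not None and cfg.lambda1 > 0:
            l_cl, d_zs_cl = triplet_loss_grad(z_spot, triplets, margin=cfg.margin_l)
            d_zs = d_zs + cfg.lambda1 * d_zs_cl
        else:
            l_cl = 0.0
        d_prelim = d_zs
        for _ in range(cfg.gcn_layers):
            d_prelim = AT @ d_prelim
        dWs, dbs = mlp.backward(d_prelim, cache)
        l_reg = (
            sum(np.sum(W**2) for W in mlp.weights) + np.sum(e_gene**2)
        ) / (2.0 * denom)
        grads = (
            [dW + cfg.lambda2 * W / denom for dW, W in zip(dWs, mlp.weights)]
            + dbs
            + [d_zg + cfg.lambda2 * e_gene / denom]
        )
        l_total = total_loss(l_mse, l_cl, l_reg, cfg.lambda1, cfg.lambda2)
        if not np.isfinite(l_total):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        log.record(l_mse, l_cl, float(l_reg), l_total)
        opt.step(grads)
    prelim, _ = mlp.forward(X)
    state = EmbeddingState(init_spot=prelim, init_gene=e_gene)
    state.final_spot = spatial_gcn(prelim, A, layers=cfg.gcn_layers)
    state.final_gene = e_gene
    return state, log
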