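"""Spot-gene bipartite graph construction and edge subgraph sampling.

Each slice contributes a binary incidence matrix R^b (spot i -- gene j edge
iff gene j is expressed in spot i).  All slices attach to one shared set of
gene nodes, so spots of different slices become indirectly connected through
co-expressed genes; gene degree is therefore pooled over slices.  Spot-spot
and gene-gene edges never exist.

For the reconstruction loss a fixed fraction of the observed edges is sampled
per slice (the positive subgraph) together with an equal number of uniformly
drawn non-edges (the negative subgraph).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass
class HeteroGraph:
    """Combined multi-slice bipartite spot-gene graph.

    ``incidence[b]`` is the CSR binary matrix R^b of slice b (n_spots_b x G).
    Degrees: ``spot_degrees[b][i]`` = number of genes expressed in spot i;
    ``gene_degrees[j]`` = number of (slice, spot) pairs expressing gene j,
    pooled over slices.  The dense (Nb+G)^2 block adjacency is never built;
    neighbour and degree queries go through the sparse incidences.
    """

    incidence: list[sp.csr_matrix]
    n_genes: int

    def __post_init__(self) -> None:
        for R in self.incidence:
            if R.shape[1] != self.n_genes:
                raise ValueError(
                    f"inconsistent gene axis: {R.shape[1]} != {self.n_genes}"
                )
        self.spot_degrees = [
            np.asarray(R.sum(axis=1)).ravel() for R in self.incidence
        ]
        self.gene_degrees = np.sum(
            [np.asarray(R.sum(axis=0)).ravel() for R in self.incidence], axis=0
        )

    @property
    def n_slices(self) -> int:
        return len(self.incidence)

    @property
    def n_spots(self) -> list[int]:
        return [R.shape[0] for R in self.incidence]

    @property
    def n_total_spots(self) -> int:
        return sum(self.n_spots)

    def edge_count(self, b: int) -> int:
        return int(self.incidence[b].nnz)

    def total_edges(self) -> int:
        return sum(self.edge_count(b) for b in range(self.n_slices))

    def edge_list(self) -> np.ndarray:
        """All observed edges as (slice, spot, gene) integer triples."""
        rows = []
        for b, R in enumerate(self.incidence):
            coo = R.tocoo()
            rows.append(
                np.column_stack([np.full(coo.nnz, b), coo.row, coo.col])
            )
        return np.vstack(rows).astype(int)


@dataclass
class EdgeSubgraphs:
    """Sampled positive (observed) and negative (absent) edge sets per slice."""

    positive_edges: list[np.ndarray]  # per slice, (n, 2) of (spot, gene)
    negative_edges: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        for pos, neg in zip(self.positive_edges, self.negative_edges):
            if len(pos) != len(neg):
                raise ValueError("positive/negative edge counts differ")


def binarize_edges(expr_matrices: list[np.ndarray]) -> list[sp.csr_matrix]:
    """Binary incidence per slice: 1 iff the gene has nonzero expression.

    Invariant to any positive rescaling of expression, so raw counts and
    normalized values produce the same incidence.
    """
    out = []
    for b, X in enumerate(expr_matrices):
        X = np.asarray(X)
        R = sp.csr_matrix((X != 0).astype(np.float64))
        empty = np.asarray(R.sum(axis=1)).ravel() == 0
        if empty.any():
            warnings.warn(
                f"slice {b}: {int(empty.sum())} spots express no gene "
                "(isolated spot nodes)"
            )
        out.append(R)
    return out


def assemble_adjacency(per_slice_incidence: list[sp.csr_matrix]) -> HeteroGraph:
    """Combine per-slice bipartite graphs over the shared gene node set."""
    if not per_slice_incidence:
        raise ValueError("no slices")
    G = per_slice_incidence[0].shape[1]
    for R in per_slice_incidence[1:]:
        if R.shape[1] != G:
            raise ValueError(
                f"slices disagree on gene count: {R.shape[1]} != {G}"
            )
    return HeteroGraph(incidence=[R.tocsr() for R in per_slice_incidence], n_genes=G)


def dense_block_adjacency(graph: HeteroGraph, b: int) -> np.ndarray:
    """Dense (Nb+G) x (Nb+G) block adjacency of one slice — small graphs only.

    Layout [[0, R], [R^T, 0]]; used by tests as an oracle, never by the
    propagation path.
    """
    R = graph.incidence[b].toarray()
    nb = R.shape[0]
    C = np.zeros((nb + graph.n_genes, nb + graph.n_genes))
    C[:nb, nb:] = R
    C[nb:, :nb] = R.T
    return C


def sample_edge_subgraphs(
    graph: HeteroGraph, fraction: float = 0.10, seed: int = 0
) -> EdgeSubgraphs:
    """Sample ``fraction`` of each slice's observed edges plus matched non-edges.

    Positives are a uniform draw without replacement; negatives are rejection-
    sampled uniformly from the (spot, gene) complement and verified against
    the incidence, so the two sets never overlap.  Fully reproducible from
    ``seed``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    positives, negatives = [], []
    for b, R in enumerate(graph.incidence):
        nb, G = R.shape
        n_edges = R.nnz
        if n_edges < 10:
            raise ValueError(f"slice {b} has only {n_edges} observed edges")
        n_pick = max(1, int(np.floor(fraction * n_edges)))
        n_absent = nb * G - n_edges
        if n_absent < n_pick:
            raise ValueError(
                f"slice {b}: graph too dense, only {n_absent} non-edges "
                f"available but {n_pick} needed"
            )
        coo = R.tocoo()
        idx = rng.choice(n_edges, size=n_pick, replace=False)
        positives.append(np.column_stack([coo.row[idx], coo.col[idx]]))

        dense_lookup = R.toarray() if nb * G <= 4_000_000 else None
        neg: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        while len(neg) < n_pick:
            draw = max(2 * (n_pick - len(neg)), 16)
            spots = rng.integers(0, nb, size=draw)
            genes = rng.integers(0, G, size=draw)
            if dense_lookup is not None:
                present = dense_lookup[spots, genes] != 0
            else:
                present = np.asarray(R[spots, genes]).ravel() != 0
            for i, j, p in zip(spots, genes, present):
                if p or (i, j) in seen:
                    continue
                seen.add((int(i), int(j)))
                neg.append((int(i), int(j)))
                if len(neg) == n_pick:
                    break
        negatives.append(np.array(neg, dtype=int))
    return EdgeSubgraphs(positive_edges=positives, negative_edges=negatives, seed=seed)
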