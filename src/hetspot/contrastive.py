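"""Triplet construction and the contrastive margin loss.

Anchors are spots.  Intra-slice positives are each anchor's k nearest
neighbours in the preprocessed feature space (PCA scores by default);
negatives are drawn uniformly from spots whose Louvain precluster differs
from the anchor's.  For multi-slice data, cross-slice anchor-positive pairs
come from mutual nearest neighbours (MNN) in an L2-normalized CCA space
obtained by randomized SVD of the cross-slice similarity matrix
``Y = X_b1 X_b2^T``.  The loss is the summed triplet hinge
``max(d(a,p) - d(a,n) + margin, 0)`` on the final spot embeddings.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.utils.extmath import randomized_svd


@dataclass
class CcaPair:
    """CCA-style joint embedding of two slices plus their MNN pairs."""

    slice_pair: tuple[int, int]
    U1: np.ndarray
    U2: np.ndarray
    singular_values: np.ndarray
    mnn_pairs: np.ndarray  # (n, 2) local indices (i in b1, j in b2)


@dataclass
class PreclusterLabels:
    labels: np.ndarray
    resolution: float


@dataclass
class TripletSet:
    """Anchor/positive/negative spot triples in the global spot ordering."""

    triples: np.ndarray  # (n, 3) int
    provenance: np.ndarray  # (n,) str: "intra" | "inter"

    def __len__(self) -> int:
        return len(self.triples)


# ---------------------------------------------------------------------------
# CCA + MNN


def cca_embed(
    X_b1: np.ndarray,
    X_b2: np.ndarray,
    d_cca: int | None = None,
    seed: int = 0,
    slice_pair: tuple[int, int] = (0, 1),
) -> CcaPair:
    """Joint low-rank embedding of two slices from their cross-product.

    ``Y = X_b1 @ X_b2.T`` captures cross-slice spot similarity; a randomized
    SVD of rank ``d_cca`` (default min(50, N1, N2)) yields the two score
    matrices, whose rows are L2-normalized before MNN search.
    """
    X_b1 = np.asarray(X_b1, dtype=float)
    X_b2 = np.asarray(X_b2, dtype=float)
    if X_b1.shape[1] != X_b2.shape[1]:
        raise ValueError("slices must share the feature axis")
    n1, n2 = X_b1.shape[0], X_b2.shape[0]
    if d_cca is None:
        d_cca = min(50, n1, n2)
    if d_cca > min(n1, n2):
        warnings.warn(f"d_cca={d_cca} exceeds min slice size; reducing")
        d_cca = min(n1, n2)
    Y = X_b1 @ X_b2.T
    if not np.any(Y):
        warnings.warn("zero cross-slice similarity matrix: no shared structure")
    U1, S, V2t = randomized_svd(
        Y, n_components=d_cca, n_oversamples=10, n_iter=4, random_state=seed
    )
    U2 = V2t.T
    return CcaPair(
        slice_pair=slice_pair,
        U1=_l2_normalize_rows(U1),
        U2=_l2_normalize_rows(U2),
        singular_values=S,
        mnn_pairs=np.empty((0, 2), dtype=int),
    )


def _l2_normalize_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def _topk_indices(dist: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k smallest, ties broken by lower column index."""
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def mutual_nearest_neighbors(
    U1: np.ndarray, U2: np.ndarray, k_mnn: int = 5
) -> np.ndarray:
    """Cross-set pairs (i, j) mutually within each other's k nearest rows."""
    dist = cdist(U1, U2)
    k1 = min(k_mnn, U2.shape[0])
    k2 = min(k_mnn, U1.shape[0])
    top12 = _topk_indices(dist, k1)  # per row of U1, nearest in U2
    top21 = _topk_indices(dist.T, k2)  # per row of U2, nearest in U1
    in21 = [set(row.tolist()) for row in top21]
    pairs = [
        (i, int(j))
        for i in range(U1.shape[0])
        for j in top12[i]
        if i in in21[int(j)]
    ]
    if not pairs:
        warnings.warn("no mutual nearest neighbours found between slices")
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(pairs), dtype=int)


def select_representatives(group_sizes: list[list[int]]) -> list[int]:
    """Index (within each group) of the slice with the most spots.

    Ties broken by input order, matching the rule that the largest slice
    represents its group in cross-group alignment.
    """
    return [int(np.argmax(sizes)) for sizes in group_sizes]


def plan_mnn_pairs(
    slice_sizes: list[int], groups: list[int] | None = None
) -> list[tuple[int, int]]:
    """Which slice pairs get an MNN computation.

    All pairs within a group, then representative-vs-representative across
    groups.  Default grouping treats all slices as one group.
    """
    B = len(slice_sizes)
    if groups is None:
        groups = [0] * B
    group_ids = sorted(set(groups))
    members = {g: [b for b in range(B) if groups[b] == g] for g in group_ids}
    pairs: list[tuple[int, int]] = []
    for g in group_ids:
        ms = members[g]
        pairs.extend((ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms)))
    reps = [
        members[g][int(np.argmax([slice_sizes[b] for b in members[g]]))]
        for g in group_ids
    ]
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            pairs.append((min(reps[i], reps[j]), max(reps[i], reps[j])))
    # dedupe, keep order
    seen: set[tuple[int, int]] = set()
    out = []
    for p in pairs:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# intra-slice positives / negatives


def intra_slice_positives(features: np.ndarray, k_knn: int = 20) -> np.ndarray:
    """Each spot's k nearest same-slice spots (Euclidean, ties by index)."""
    n = features.shape[0]
    if k_knn >= n:
        warnings.warn(f"k_knn={k_knn} >= n_spots={n}; clamping to {n - 1}")
        k_knn = n - 1
    dist = cdist(features, features)
    np.fill_diagonal(dist, np.inf)
    return _topk_indices(dist, k_knn)


def louvain_preclusters(
    features: np.ndarray, k_graph: int = 20, resolution: float = 1.0, seed: int = 0
) -> PreclusterLabels:
    """Louvain communities of the unweighted k-NN graph of the features."""
    nbrs = intra_slice_positives(features, k_knn=min(k_graph, features.shape[0] - 1))
    edges = {
        (min(i, int(j)), max(i, int(j)))
        for i in range(features.shape[0])
        for j in nbrs[i]
    }
    g = igraph.Graph(n=features.shape[0], edges=sorted(edges))
    random.seed(seed)  # igraph draws from Python's random module
    part = g.community_multilevel(resolution=resolution)
    return PreclusterLabels(
        labels=np.asarray(part.membership, dtype=int), resolution=resolution
    )


def louvain_negatives(
    features: np.ndarray,
    k_knn: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    preclusters: PreclusterLabels | None = None,
) -> np.ndarray:
    """Per-anchor negatives sampled from spots outside the anchor's precluster.

    Returns an (n_spots, k_knn) index array; raises when Louvain finds a
    single community (increase the resolution).
    """
    if preclusters is None:
        preclusters = louvain_preclusters(
            features, k_graph=k_knn, resolution=resolution, seed=seed
        )
    labels = preclusters.labels
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "Louvain found a single community; negatives need >= 2 preclusters "
            "(try a higher resolution)"
        )
    rng = np.random.default_rng(seed)
    n = len(labels)
    k_eff = min(k_knn, n - 1)
    out = np.empty((n, k_eff), dtype=int)
    for c in np.unique(labels):
        pool = np.flatnonzero(labels != c)
        members = np.flatnonzero(labels == c)
        out[members] = rng.choice(pool, size=(len(members), k_eff), replace=True)
    return out


# ---------------------------------------------------------------------------
# triplet assembly and loss


def build_triplets(
    positives: list[np.ndarray],
    negatives: list[np.ndarray],
    offsets: np.ndarray,
    mnn_pairs: list[tuple[tuple[int, int], np.ndarray]] | None = None,
    mode: str = "single",
) -> TripletSet:
    """Assemble the triplet set in global spot indices.

    Intra-slice: anchor a's t-th positive is matched with a's t-th sampled
    negative.  Multi mode additionally turns every MNN pair (i in b1, j in
    b2) into triples in both directions with the partner as positive and the
    anchor's sampled (same-slice) negatives as negatives — one triple per
    negative, mirroring the intra-slice anchors' k_knn triples each.
    """
    if mode not in {"single", "multi"}:
        raise ValueError("mode must be 'single' or 'multi'")
    triples: list[tuple[int, int, int]] = []
    prov: list[str] = []
    for b, (pos, neg) in enumerate(zip(positives, negatives)):
        off = int(offsets[b])
        n, k = pos.shape
        kk = min(k, neg.shape[1])
        for a in range(n):
            for t in range(kk):
                triples.append((off + a, off + int(pos[a, t]), off + int(neg[a, t])))
                prov.append("intra")
    if mode == "multi" and mnn_pairs:
        for (b1, b2), pairs in mnn_pairs:
            o1, o2 = int(offsets[b1]), int(offsets[b2])
            for i, j in pairs:
                for ni in negatives[b1][int(i)]:
                    triples.append((o1 + int(i), o2 + int(j), o1 + int(ni)))
                    prov.append("inter")
                for nj in negatives[b2][int(j)]:
                    triples.append((o2 + int(j), o1 + int(i), o2 + int(nj)))
                    prov.append("inter")
    if not triples:
        raise ValueError("empty triplet set: the contrastive loss is undefined")
    return TripletSet(
        triples=np.array(triples, dtype=int), provenance=np.array(prov)
    )


def triplet_loss(
    z_spot: np.ndarray, triplets: TripletSet, margin: float = 1.0
) -> float:
    """Summed hinge: max(||z_a - z_p|| - ||z_a - z_n|| + margin, 0)."""
    t = triplets.triples
    d_ap = np.linalg.norm(z_spot[t[:, 0]] - z_spot[t[:, 1]], axis=1)
    d_an = np.linalg.norm(z_spot[t[:, 0]] - z_spot[t[:, 2]], axis=1)
    return float(np.maximum(d_ap - d_an + margin, 0.0).sum())


def _scatter_matrix(indices: np.ndarray, n_rows: int):
    """Sparse S with S[indices[e], e] = 1; S @ V accumulates V rows by index."""
    import scipy.sparse as sp

    m = len(indices)
    return sp.csr_matrix(
        (np.ones(m), (indices, np.arange(m))), shape=(n_rows, m)
    )


def triplet_loss_grad(
    z_spot: np.ndarray, triplets: TripletSet, margin: float = 1.0
) -> tuple[float, np.ndarray]:
    """Loss plus its (sub)gradient w.r.t. the spot embeddings.

    The scatter of per-triple contributions back onto spots is a fixed linear
    map, precomputed as three sparse matrices and cached on the triplet set.
    """
    t = triplets.triples
    n = z_spot.shape[0]
    cache = getattr(triplets, "_scatter_cache", None)
    if cache is None or cache[0] != n:
        cache = (
            n,
            _scatter_matrix(t[:, 0], n),
            _scatter_matrix(t[:, 1], n),
            _scatter_matrix(t[:, 2], n),
        )
        triplets._scatter_cache = cache  # type: ignore[attr-defined]
    _, Sa, Sp, Sn = cache
    diff_ap = z_spot[t[:, 0]] - z_spot[t[:, 1]]
    diff_an = z_spot[t[:, 0]] - z_spot[t[:, 2]]
    d_ap = np.sqrt(np.einsum("ij,ij->i", diff_ap, diff_ap))
    d_an = np.sqrt(np.einsum("ij,ij->i", diff_an, diff_an))
    hinge = d_ap - d_an + margin
    active = hinge > 0
    loss = float(hinge[active].sum())
    eps = 1e-12
    u_ap = np.where(active, 1.0, 0.0)[:, None] * diff_ap / (d_ap[:, None] + eps)
    u_an = np.where(active, 1.0, 0.0)[:, None] * diff_an / (d_an[:, None] + eps)
    grad = Sa @ (u_ap - u_an) - Sp @ u_ap + Sn @ u_an
    return loss, grad
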