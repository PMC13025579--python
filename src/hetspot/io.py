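"""Slice loading, preprocessing and spatial-graph construction.

A *slice* is one tissue section of a spatially resolved transcriptomics (SRT)
experiment: a spot x gene count matrix plus a 2-D coordinate per spot.  This
module reads slices from standard on-disk formats (AnnData ``.h5ad``,
MatrixMarket + name lists, dense CSV/TSV), harmonizes the gene vocabulary
across slices, selects highly variable genes, normalizes counts by a
median-scaled library factor, reduces dimensionality with a joint PCA and
builds the per-slice spatial k-nearest-neighbour graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.spatial.distance import cdist


@dataclass
class SliceData:
    """One slice's raw counts, normalized expression and spot geometry.

    ``raw_counts`` holds non-negative counts (spots x genes), ``norm_expr``
    the library-normalized log values, ``coords`` the platform-unit 2-D spot
    positions.  ``labels`` optionally carries ground-truth domain annotation.
    """

    slice_id: str
    raw_counts: np.ndarray
    coords: np.ndarray
    spot_names: list[str]
    gene_names: list[str]
    norm_expr: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.raw_counts.ndim != 2:
            raise ValueError("raw_counts must be 2-D (spots x genes)")
        if (self.raw_counts < 0).any():
            raise ValueError("raw_counts contains negative entries")
        n = self.raw_counts.shape[0]
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"slice {self.slice_id!r}: {n} spots but coords shape "
                f"{self.coords.shape}"
            )
        if len(self.spot_names) != n:
            raise ValueError("spot_names length mismatch")
        if len(self.gene_names) != self.raw_counts.shape[1]:
            raise ValueError("gene_names length mismatch")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length mismatch")

    @property
    def n_spots(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.raw_counts.shape[1]


@dataclass
class MultiSliceDataset:
    """An ordered collection of slices sharing one gene vocabulary."""

    slices: list[SliceData]
    pca_embed: list[np.ndarray] | None = None
    hvg_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("dataset needs at least one slice")
        ref = self.slices[0].gene_names
        for s in self.slices[1:]:
            if s.gene_names != ref:
                raise ValueError("slices do not share an identical gene axis")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def gene_names(self) -> list[str]:
        return self.slices[0].gene_names

    @property
    def n_total_spots(self) -> int:
        return sum(s.n_spots for s in self.slices)

    def spot_offsets(self) -> np.ndarray:
        """Global index of each slice's first spot in concatenation order."""
        return np.concatenate(
            [[0], np.cumsum([s.n_spots for s in self.slices])[:-1]]
        ).astype(int)


@dataclass
class SpatialGraph:
    """Undirected spatial proximity graph over one slice's spots.

    ``neighbor_sets[i]`` lists the neighbours of spot ``i`` after symmetrizing
    the directed k-NN relation by edge union; ``edges`` is the (i, j), i < j
    undirected edge list.
    """

    slice_id: str
    neighbor_sets: list[np.ndarray]
    edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.edges is None:
            pairs = {
                (min(i, int(j)), max(i, int(j)))
                for i, nbrs in enumerate(self.neighbor_sets)
                for j in nbrs
            }
            self.edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)

    @property
    def n_spots(self) -> int:
        return len(self.neighbor_sets)


# ---------------------------------------------------------------------------
# loading


def _read_expression(spec: dict) -> tuple[np.ndarray, list[str], list[str], np.ndarray | None, np.ndarray | None]:
    """Return (counts, spot_names, gene_names, coords-or-None, labels-or-None)."""
    path = Path(spec["expression"])
    suffix = path.suffix.lower()
    if suffix == ".h5ad":
        adata = ad.read_h5ad(path)
        layer = spec.get("layer")
        X = adata.layers[layer] if layer else adata.X
        counts = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        coords = None
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=float)
        labels = None
        label_key = spec.get("label_key", "domain")
        if label_key in adata.obs:
            labels = np.asarray(adata.obs[label_key])
        return (
            counts.astype(float),
            [str(s) for s in adata.obs_names],
            [str(g) for g in adata.var_names],
            coords,
            labels,
        )
    if suffix == ".mtx":
        from scipy.io import mmread

        mat = sp.csr_matrix(mmread(path))
        genes = pd.read_csv(spec["genes"], header=None, sep="\t")[0].astype(str).tolist()
        spots = pd.read_csv(spec["spots"], header=None, sep="\t")[0].astype(str).tolist()
        counts = np.asarray(mat.todense(), dtype=float)
        if counts.shape == (len(genes), len(spots)) and counts.shape[0] != counts.shape[1]:
            counts = counts.T  # genes x spots convention on disk
        return counts, spots, genes, None, None
    if suffix in {".csv", ".tsv", ".txt"}:
        sep = "," if suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return (
            df.to_numpy(dtype=float),
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
            None,
            None,
        )
    raise ValueError(f"unsupported expression format: {path}")


def _read_coords(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        return df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    return df.iloc[:, -2:].to_numpy(dtype=float)


def load_slices(source_specs: Sequence[dict]) -> MultiSliceDataset:
    """Load one or more slices and harmonize them to a shared gene axis.

    Each descriptor is a dict with keys ``expression`` (``.h5ad``, ``.mtx`` or
    dense CSV/TSV path), optional ``coords`` (CSV with x,y columns; required
    unless the h5ad carries a spatial slot), optional ``genes``/``spots`` name
    lists for MTX, optional ``slice_id``, ``layer`` and ``label_key``.

    Gene vocabularies are intersected across slices (order taken from the
    first slice); spots with zero total counts are dropped with a warning.
    """
    slices: list[SliceData] = []
    for idx, spec in enumerate(source_specs):
        counts, spot_names, gene_names, coords, labels = _read_expression(spec)
        if spec.get("coords"):
            coords = _read_coords(spec["coords"])
        if coords is None:
            raise ValueError(
                f"slice {idx}: no coordinates (neither a spatial slot nor a coords file)"
            )
        if coords.shape[0] != counts.shape[0]:
            raise ValueError(
                f"slice {idx}: {counts.shape[0]} spots but {coords.shape[0]} coordinate rows"
            )
        if spec.get("labels"):
            labels = pd.read_csv(spec["labels"]).iloc[:, -1].to_numpy()
        slices.append(
            SliceData(
                slice_id=str(spec.get("slice_id", f"slice{idx}")),
                raw_counts=counts,
                coords=coords,
                spot_names=spot_names,
                gene_names=gene_names,
                labels=labels,
            )
        )
    return harmonize(slices)


def harmonize(slices: list[SliceData]) -> MultiSliceDataset:
    """Restrict every slice to the shared gene set and drop empty spots."""
    shared = set(slices[0].gene_names)
    for s in slices[1:]:
        shared &= set(s.gene_names)
    if not shared:
        raise ValueError("empty gene intersection across slices")
    order = [g for g in slices[0].gene_names if g in shared]
    out = []
    for s in slices:
        col = [s.gene_names.index(g) for g in order] if s.gene_names != order else None
        counts = s.raw_counts[:, col] if col is not None else s.raw_counts
        keep = counts.sum(axis=1) > 0
        if not keep.all():
            warnings.warn(
                f"slice {s.slice_id!r}: dropping {int((~keep).sum())} spots with zero total counts"
            )
        out.append(
            SliceData(
                slice_id=s.slice_id,
                raw_counts=counts[keep],
                coords=s.coords[keep],
                spot_names=[n for n, k in zip(s.spot_names, keep) if k],
                gene_names=order,
                labels=None if s.labels is None else np.asarray(s.labels)[keep],
            )
        )
    return MultiSliceDataset(slices=out)


# ---------------------------------------------------------------------------
# preprocessing


def select_hvgs(dataset: MultiSliceDataset, n_hvg: int = 2000) -> MultiSliceDataset:
    """Keep the top ``n_hvg`` highly variable genes, selected jointly.

    Dispersion-based (seurat-flavor) selection is run on the spot-wise
    concatenation of all slices so that every slice keeps the same gene set —
    the heterogeneous graph requires one shared gene node vocabulary.  When
    fewer genes than ``n_hvg`` are present, all genes are kept.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    counts = np.vstack([s.raw_counts for s in dataset.slices])
    if counts.sum() == 0:
        raise ValueError("all-zero expression matrix: no variable genes")
    n_genes = counts.shape[1]
    if n_genes <= n_hvg:
        mask = np.ones(n_genes, dtype=bool)
    else:
        adata = ad.AnnData(X=counts.copy())
        adata.var_names = dataset.gene_names
        sc.pp.normalize_total(adata)
        sc.pp.log1p(adata)
        sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_hvg)
        mask = adata.var["highly_variable"].to_numpy()
    keep_idx = np.flatnonzero(mask)
    genes = [dataset.gene_names[i] for i in keep_idx]
    slices = [
        SliceData(
            slice_id=s.slice_id,
            raw_counts=s.raw_counts[:, keep_idx],
            coords=s.coords,
            spot_names=s.spot_names,
            gene_names=genes,
            labels=s.labels,
        )
        for s in dataset.slices
    ]
    return MultiSliceDataset(slices=slices, hvg_mask=mask)


def compute_library_factors(raw_counts: np.ndarray) -> np.ndarray:
    """Per-spot library size factor: row total / median row total.

    A spot whose total equals the median gets factor 1; zero-total spots get
    factor 0 and are left all-zero by :func:`normalize_log`.
    """
    totals = np.asarray(raw_counts, dtype=float).sum(axis=1)
    if not (totals > 0).any():
        raise ValueError("no spot with positive total counts")
    med = np.median(totals)
    return totals / med


def normalize_log(raw_counts: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Library-normalize and natural-log transform: x = log(count / lib + 1)."""
    raw = np.asarray(raw_counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    zero = factors == 0
    if zero.any() and raw[zero].sum() > 0:
        raise AssertionError("zero library factor on a spot with nonzero counts")
    safe = np.where(zero, 1.0, factors)
    return np.log1p(raw / safe[:, None])


def reduce_pca(
    dataset: MultiSliceDataset, d: int = 200, seed: int = 0
) -> MultiSliceDataset:
    """Joint PCA of the normalized expression of all slices.

    Slices are concatenated along spots before the decomposition so every
    slice is scored in one shared basis.  The sign of each component is fixed
    so its largest-magnitude loading is non-negative, making the scores
    deterministic.
    """
    from sklearn.decomposition import PCA

    for s in dataset.slices:
        if s.norm_expr is None:
            raise ValueError("run preprocessing (normalize_log) before PCA")
    X = np.vstack([s.norm_expr for s in dataset.slices])
    max_d = min(X.shape[0], X.shape[1])
    if d > max_d:
        raise ValueError(f"d={d} exceeds min(n_spots, n_genes)={max_d}")
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component >= 0
    comp = pca.components_
    flip = np.sign(comp[np.arange(d), np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    offsets = dataset.spot_offsets()
    embeds = [
        scores[o : o + s.n_spots] for o, s in zip(offsets, dataset.slices)
    ]
    dataset.pca_embed = embeds
    return dataset


def preprocess(
    dataset: MultiSliceDataset,
    n_hvg: int = 2000,
    pca_d: int = 200,
    seed: int = 0,
) -> MultiSliceDataset:
    """HVG selection, library normalization and joint PCA in one call."""
    dataset = select_hvgs(dataset, n_hvg=n_hvg)
    for s in dataset.slices:
        factors = compute_library_factors(s.raw_counts)
        s.norm_expr = normalize_log(s.raw_counts, factors)
    pca_d = min(pca_d, dataset.n_total_spots, len(dataset.gene_names))
    return reduce_pca(dataset, d=pca_d, seed=seed)


# ---------------------------------------------------------------------------
# spatial graph


def build_spatial_graph(
    coords: np.ndarray, k: int = 7, slice_id: str = "slice0"
) -> SpatialGraph:
    """Symmetrized k-nearest-neighbour graph over spot coordinates.

    Each spot's k smallest Euclidean distances (ties broken by lower spot
    index) define directed edges; the union of directed edges gives the
    undirected graph.  ``k`` is clamped to n_spots - 1 with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots for a spatial graph")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if k >= n:
        warnings.warn(f"k={k} >= n_spots={n}; clamping to {n - 1}")
        k = n - 1
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    # stable sort on (distance, index) -> deterministic ties
    order = np.argsort(dist, axis=1, kind="stable")
    knn = order[:, :k]
    neighbor_sets: list[set[int]] = [set(row.tolist()) for row in knn]
    for i, row in enumerate(knn):
        for j in row:
            neighbor_sets[int(j)].add(i)
    return SpatialGraph(
        slice_id=slice_id,
        neighbor_sets=[np.array(sorted(s_), dtype=int) for s_ in neighbor_sets],
    )


def build_spatial_graphs(dataset: MultiSliceDataset, k: int = 7) -> list[SpatialGraph]:
    return [
        build_spatial_graph(s.coords, k=k, slice_id=s.slice_id)
        for s in dataset.slices
    ]


# ---------------------------------------------------------------------------
# writer


def to_anndata(
    dataset: MultiSliceDataset,
    embeddings: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> ad.AnnData:
    """Assemble the processed dataset into one AnnData over all spots."""
    counts = np.vstack([s.raw_counts for s in dataset.slices])
    adata = ad.AnnData(X=counts)
    adata.var_names = dataset.gene_names
    adata.obs_names = [
        f"{s.slice_id}:{n}" for s in dataset.slices for n in s.spot_names
    ]
    adata.obs["slice_id"] = np.repeat(
        [s.slice_id for s in dataset.slices],
        [s.n_spots for s in dataset.slices],
    )
    adata.obsm["spatial"] = np.vstack([s.coords for s in dataset.slices])
    if all(s.norm_expr is not None for s in dataset.slices):
        adata.layers["norm_expr"] = np.vstack([s.norm_expr for s in dataset.slices])
    if dataset.pca_embed is not None:
        adata.obsm["X_pca"] = np.vstack(dataset.pca_embed)
    if embeddings is not None:
        adata.obsm["X_embed"] = np.asarray(embeddings)
    if labels is not None:
        adata.obs["cluster"] = pd.Categorical([str(c) for c in labels])
    truth = [s.labels for s in dataset.slices]
    if all(t is not None for t in truth):
        adata.obs["domain"] = pd.Categorical(
            [str(v) for t in truth for v in t]  # type: ignore[union-attr]
        )
    return adata
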