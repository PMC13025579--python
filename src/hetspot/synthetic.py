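"""Synthetic SRT data generator with known spatial domains.

Emulates the structure the pipeline is designed for: spatially contiguous
layered domains (cortical-layer-like bands across the tissue), domain-
specific marker gene programs over a shared gene vocabulary, negative-
binomial count noise with per-spot library-size variation, zero-inflation
dropout, and — for multi-slice data — slice-specific multiplicative gene-wise
batch scaling.  Everything is driven by a single seed via spawned
``SeedSequence`` streams so slices are independent but fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MultiSliceDataset, SliceData


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give an easy 3-domain banded slice.

    ``grid`` is (rows, cols) for a regular lattice, or None with ``n_spots``
    for uniform random positions in the unit square.  ``dispersion`` is the
    negative-binomial size parameter (larger = closer to Poisson).
    """

    n_slices: int = 1
    grid: tuple[int, int] | None = (25, 20)
    n_spots: int | None = None
    n_domains: int = 3
    domain_geometry: str = "layered-bands"
    n_genes: int = 200
    markers_per_domain: int = 20
    base_rate: float = 1.0
    marker_fold: float = 5.0
    dropout: float = 0.3
    dispersion: float = 10.0
    batch_scale_sd: float = 0.0
    libsize_sd: float = 0.3
    seed: int = 0
    shared_domains: bool = True

    def __post_init__(self) -> None:
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if not (0 <= self.dropout <= 1):
            raise ValueError("dropout must be a probability")
        if self.domain_geometry not in {"layered-bands", "voronoi"}:
            raise ValueError("domain_geometry must be 'layered-bands' or 'voronoi'")
        if self.n_domains * self.markers_per_domain > self.n_genes:
            raise ValueError("marker genes exceed the gene vocabulary")
        if self.grid is None and self.n_spots is None:
            raise ValueError("give either grid or n_spots")

    @property
    def spots_per_slice(self) -> int:
        return self.grid[0] * self.grid[1] if self.grid else int(self.n_spots)


def _coords(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.grid is not None:
        rows, cols = spec.grid
        yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    return rng.uniform(0.0, 1.0, size=(spec.n_spots, 2))


def _domain_labels(
    spec: SyntheticSpec, coords: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    y = coords[:, 1]
    if spec.domain_geometry == "layered-bands":
        # equal-width bands along y: mirrors layered cortical architecture
        lo, hi = y.min(), y.max()
        edges = np.linspace(lo, hi, spec.n_domains + 1)
        labels = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, spec.n_domains - 1)
        return labels.astype(int)
    centers = rng.uniform(coords.min(0), coords.max(0), size=(spec.n_domains, 2))
    d = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return np.argmin(d, axis=1).astype(int)


def _marker_assignment(spec: SyntheticSpec) -> np.ndarray:
    """Gene -> owning domain (-1 for background), deterministic block layout."""
    owner = np.full(spec.n_genes, -1, dtype=int)
    for dom in range(spec.n_domains):
        start = dom * spec.markers_per_domain
        owner[start : start + spec.markers_per_domain] = dom
    return owner


def generate_slice(
    spec: SyntheticSpec, slice_index: int = 0, rng: np.random.Generator | None = None
) -> SliceData:
    """One slice with ground-truth labels; fully seeded.

    Mean model: background genes at ``base_rate``, markers elevated by
    ``marker_fold`` inside their domain; per-spot log-normal library factors
    and (if requested) per-slice log-normal gene scalings multiply the mean,
    counts are negative-binomial and then zero-inflated with prob ``dropout``.
    """
    if rng is None:
        seq = np.random.SeedSequence(spec.seed).spawn(spec.n_slices)[slice_index]
        rng = np.random.default_rng(seq)
    coords = _coords(spec, rng)
    labels = _domain_labels(spec, coords, rng)
    owner = _marker_assignment(spec)
    n = coords.shape[0]
    mu = np.full((n, spec.n_genes), spec.base_rate, dtype=float)
    for dom in range(spec.n_domains):
        genes = owner == dom
        spots = labels == dom
        mu[np.ix_(spots, genes)] *= spec.marker_fold
    lib = rng.lognormal(0.0, spec.libsize_sd, size=n)
    mu *= lib[:, None]
    if spec.batch_scale_sd > 0:
        gene_scale = rng.lognormal(0.0, spec.batch_scale_sd, size=spec.n_genes)
        mu *= gene_scale[None, :]
    theta = spec.dispersion
    if spec.dropout >= 1.0:
        counts = np.zeros_like(mu)
    else:
        p = theta / (theta + mu)
        counts = rng.negative_binomial(theta, p).astype(float)
        if spec.dropout > 0:
            counts *= rng.random(counts.shape) >= spec.dropout
    return SliceData(
        slice_id=f"synth{slice_index}",
        raw_counts=counts,
        coords=coords,
        spot_names=[f"s{slice_index}_spot{i}" for i in range(n)],
        gene_names=[f"gene{j}" for j in range(spec.n_genes)],
        labels=labels,
    )


def generate_multislice(spec: SyntheticSpec) -> MultiSliceDataset:
    """Slices share the gene vocabulary and domain layout; batch effects differ."""
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_slices)
    slices = [
        generate_slice(spec, slice_index=b, rng=np.random.default_rng(seqs[b]))
        for b in range(spec.n_slices)
    ]
    # drop spots that ended up all-zero (dropout can empty a spot)
    cleaned = []
    for s in slices:
        keep = s.raw_counts.sum(axis=1) > 0
        cleaned.append(
            SliceData(
                slice_id=s.slice_id,
                raw_counts=s.raw_counts[keep],
                coords=s.coords[keep],
                spot_names=[n for n, k in zip(s.spot_names, keep) if k],
                gene_names=s.gene_names,
                labels=s.labels[keep],
            )
        )
    return MultiSliceDataset(slices=cleaned)
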