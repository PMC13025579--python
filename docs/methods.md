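# Methods

## Model overview and assumptions

`hetspot` treats spatial-domain detection as self-supervised representation
learning on two graphs built from the data:

- a **spot–gene bipartite graph**: spot $i$ of slice $b$ is linked to gene
  $j$ iff $\tilde x^b_{ij} > 0$ on the HVG-filtered count matrix.  All
  slices attach to one shared set of gene nodes, which is what couples
  unaligned slices — two spots in different sections are similar when they
  express overlapping gene sets, regardless of their coordinates.
- a **spatial k-NN graph** per slice (k = 7, Euclidean distances in
  platform units), encoding the assumption that adjacent spots tend to
  belong to the same domain.

The encoder is deliberately parameter-free: LightGCN layers only average
degree-normalized neighbour embeddings, and the spatial stage only averages
spatial neighbours.  The learnable state is the initial embedding matrix of
all spots and genes (width `d_emb`, default 64).  This keeps the model small,
makes every encoder stage an exact linear map, and concentrates all fitting
capacity in the embeddings themselves.

Key modelling assumptions: domains are characterized by which genes are
on, not only by expression magnitude (the incidence is binary); spatial
proximity is informative at the scale of k = 7 neighbours; batch effects
act mostly per gene and per spot total, which library normalization plus
cross-slice anchoring can absorb.

## Objective

$L = L_{\mathrm{MSE}} + \lambda_1 L_{\mathrm{CL}} + \lambda_2 L_{\mathrm{reg}}$

- $L_{\mathrm{MSE}}$: per slice, the mean squared error over a sampled 10%
  of observed edges plus an equal number of sampled non-edges, between the
  sigmoid-decoded scores and the targets.  The decoder lives in (0,1) while
  log-normalized expression is unbounded, so positive-edge targets are the
  normalized values divided by the slice maximum (the lower end of the
  min–max range is 0 by construction, since non-edges have zero counts);
  negative edges target exactly 0.  A `binary_targets` switch regresses the
  0/1 incidence instead.  The edge sample is drawn once per model, not per
  epoch, keeping the loss surface fixed (a config switch allows re-sampling).
- $L_{\mathrm{CL}}$: summed triplet hinge on the final spot embeddings,
  margin 1.0.
- $L_{\mathrm{reg}} = (\lVert E_s^{(0)}\rVert_F^2 +
  \lVert E_g^{(0)}\rVert_F^2) / (2(N_{\mathrm{total}} + G))$.

Gradients: every stage up to the losses is linear, so backpropagation is the
adjoint (transposed) operator chain, implemented directly with sparse
matrices; the decoder sigmoid and the hinge have closed-form derivatives.
The hinge uses the zero subgradient at its kink.  Optimization is full-batch
Adam (lr $10^{-3}$, 600 epochs by default); all tensors are NumPy arrays
and runs are bitwise reproducible from the seed.

## Parameters

| name | default | meaning |
|---|---|---|
| `n_hvg` | 2000 | highly variable genes kept (joint, seurat-flavor dispersion) |
| `pca_d` | 200 | joint PCA dimension; the feature space for kNN/Louvain/CCA |
| `spatial_k` | 7 | spatial nearest neighbours per spot |
| `K_layers` | 2 | LightGCN depth; layers combined with uniform weights 1/(K+1) |
| `gcn_layers` | 2 | spatial neighbour-averaging rounds |
| `d_emb` | 64 | embedding width; unstated upstream, chosen as a standard collaborative-filtering width that keeps decoder dot products well-scaled |
| `k_knn` | 20 | intra-slice positives per anchor; also the negative count |
| `k_mnn` | 5 | cross-slice mutual-nearest-neighbour depth |
| `louvain_r` | 1.0 | precluster resolution for negative sampling |
| `margin_l` | 1.0 | triplet hinge margin |
| `edge_fraction` | 0.10 | observed edges sampled for reconstruction |
| `lambda1`, `lambda2` | 1, 1e-3 | loss weights |
| `learning_rate`, `epochs` | 1e-3, 600 | Adam settings |
| `init_std` | 0.1 | scaled-normal initialization of the embeddings |

Design choices where the design was genuinely open:

- **HVG selection is joint** over the concatenated slices: the bipartite
  graph needs one shared gene vocabulary.
- **k-NN graphs are symmetrized by edge union**; distance ties break toward
  the lower spot index so graphs are reproducible.
- The **gene update averages over slices** (a 1/B prefactor on top of the
  pooled-degree normalization); `gene_slice_average=False` removes the
  prefactor for sensitivity analysis.  Gene degrees are always pooled over
  slices, consistent with a single shared gene node set.
- The **spatial stage has no self-loop** (a spot is replaced by its
  neighbours' mean); `self_loop=True` includes the spot itself.  Isolated
  spots keep their value.
- The decoder is evaluated **only on the sampled edge sets**; the dense
  reconstruction is materialized only for small inputs.
- **Triplets are built once** before training from the fixed PCA features,
  not per epoch.  Each intra-slice anchor contributes `k_knn` triples; each
  cross-slice MNN pair contributes `k_knn` triples per direction (partner as
  positive, the anchor's own-slice sampled negatives), so inter-slice
  anchors are constrained as strongly as intra-slice ones — with one triple
  per MNN pair the much larger intra-slice term dominates and slices remain
  separable.  Negatives are always drawn from the anchor's own slice.
- `d_cca` defaults to min(50, N1, N2); randomized SVD uses 10 oversampling
  columns and 4 power iterations, seeded.
- **mclust-style clustering is a native tied-covariance Gaussian mixture**
  (the EEE model family) fitted by EM from a seeded k-means start, rather
  than a bridge to the original R implementation; this keeps the pipeline
  single-language while staying in the same model family; labels can be
  cross-checked against the original R implementation externally.
- The **MLP ablation** replaces the graph stage with two hidden ReLU layers
  of width `d_emb` on normalized expression; gene embeddings stay free
  learnable vectors, and the regularizer covers the MLP weights and gene
  embeddings with the same scaling.

## Synthetic data

The generator emulates the data regime the method targets: a lattice (or
uniform-random) arrangement of spots, equal-width domain bands along the
y-axis (mirroring layered cortical anatomy; a Voronoi geometry is available),
a shared gene vocabulary in which each domain owns a block of marker genes
(20 per domain by default) elevated `marker_fold`-fold over the background
`base_rate`, negative-binomial counts (dispersion 10) with log-normal
per-spot library factors (sd 0.3), zero-inflation dropout, and — for
multi-slice data — independent per-slice log-normal gene-wise scalings
(`batch_scale_sd`).

It does **not** emulate: spot-level cell-type mixtures, spatially smooth
expression gradients within a domain, histology, platform-specific spot
geometries, or count-depth gradients across the tissue.  Passing the
recovery tests therefore shows the pipeline is correct and well-conditioned
on clean layered tissue with realistic count noise, not that it matches any
particular biological benchmark.

## Study conditions used by tests and the acceptance script

- Single-slice recovery: 500 spots (25x20 grid), 3 banded domains, 200
  genes, marker fold 5, dropout 0.3, 5 seeds, default training (600 epochs).
- Multi-slice integration and ablations: 2 slices x 192 spots (16x12),
  `batch_scale_sd` 0.5, dropout 0.3, K = 3, 300 training epochs (the loss
  and the recovered labels are already stable well before this point at
  this problem size), 5 seeds in the test suite and 3 in the acceptance
  script.  Batch mixing is measured as the slice-of-origin silhouette on
  the final embeddings versus on the PCA inputs.
- Numerical checks: sparse-vs-dense propagation on 21-node bipartite
  graphs (tolerance 1e-10); finite-difference gradient check on a 20-spot
  fixture with step 1e-5 and a guarded relative error (denominator
  max(|g|, 1e-3)) because central differences carry ~1e-9 absolute noise;
  ARI chance calibration over 200 random labelings of 500 spots.

## Numerical notes and degenerate inputs

- Zero-degree nodes (spots expressing no HVG, genes expressed nowhere)
  receive zero messages; their layer-0 embedding survives via the layer
  aggregation.  Zero-total spots are dropped at load with a warning.
- A zero library factor only occurs for all-zero spots; normalization
  leaves such rows zero and asserts otherwise.
- PCA components have their sign fixed (largest-magnitude loading
  non-negative), making scores deterministic across runs.
- `k` (spatial), `k_knn` and `d_cca` clamp with a warning when they exceed
  what the slice supports; K-means/GMM reject K < 2 or K > n.
- Louvain with a single community is an error instructing a higher
  resolution — negatives would otherwise be undefined.
- Silhouette/Calinski–Harabasz are reported as missing (NaN) for
  single-cluster partitions rather than raising.
- Sigmoid evaluation is split by sign for stability; extreme dot products
  saturate to 0/1 at float precision, which the MSE tolerates.

## Known limitations

- Full-batch training with dense per-slice expression matrices targets
  desk-scale data (up to a few thousand spots per slice); very large
  lattices would need minibatching and sparse expression storage.
- The binary incidence discards expression magnitude; lowly and highly
  expressed genes contribute equally to graph structure.
- The MNN stage is O(B^2) in the number of slices (mitigated by the
  representative-slice scheme for grouped designs).
- K (the number of domains) must be supplied by the user.
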