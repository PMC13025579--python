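# hetspot

Spatial-domain detection for spatially resolved transcriptomics (SRT),
covering single-slice and multi-slice experiments in one model.

SRT platforms (10x Visium, Stereo-seq, Slide-seqV2, BaristaSeq, STARmap, ...)
measure a gene-expression vector at every spatially located capture spot.
A central analysis task is to partition the spots of a tissue section into
*spatial domains* — contiguous regions with a coherent expression program,
such as cortical layers.  When several sections are profiled, the domains
should additionally be consistent across sections despite batch effects,
ideally without requiring the sections to be physically aligned.

`hetspot` addresses both settings with a spot–gene *heterogeneous bipartite
graph*: every spot of every slice is connected to the genes it expresses, so
spots of different slices become indirectly linked through shared gene nodes
and no coordinate alignment is needed.

## Model

Given slices $X^b \in \mathbb{R}^{N_b \times G}$ with coordinates
$U^b \in \mathbb{R}^{N_b \times 2}$:

1. **Preprocessing** — top-2000 highly variable genes (joint,
   dispersion-based), per-spot library factors
   $\mathrm{lib}_i = \sum_j \tilde x_{ij} / \mathrm{median}_{i'}\sum_j \tilde x_{i'j}$,
   normalization $x_{ij} = \log(\tilde x_{ij}/\mathrm{lib}_i + 1)$, joint
   PCA to $d = 200$, and a spatial $k$-NN graph per slice ($k = 7$).
2. **Heterogeneous graph** — binary incidence $r^b_{ij} = 1$ iff gene $j$
   is expressed in spot $i$; gene degrees pooled over slices.
3. **Dual-stage encoder** — $K = 2$ layers of weight-free LightGCN
   propagation with symmetric degree normalization
   $1/\sqrt{|N_s^{b,i}||N_g^j|}$, uniform layer aggregation
   $w^{(k)} = 1/(K{+}1)$, then two rounds of neighbour-mean aggregation on
   the spatial graph.  A sigmoid dot-product decoder
   $\hat x^b_{ij} = \sigma(\langle z_s^{b,i}, z_g^j\rangle)$ reconstructs
   sampled edges.
4. **Contrastive learning** — triplet hinge
   $\sum_T \max(\lVert z_a - z_p\rVert - \lVert z_a - z_n\rVert + \ell,\,0)$
   with intra-slice $k$-NN positives ($k_{\mathrm{knn}} = 20$), negatives
   drawn from other Louvain preclusters, and — for multi-slice data —
   cross-slice mutual-nearest-neighbour anchors found in an L2-normalized
   CCA space (randomized SVD of $X^{b_1} X^{b_2 \top}$).
5. **Objective** — $L = L_{\mathrm{MSE}} + \lambda_1 L_{\mathrm{CL}} +
   \lambda_2 L_{\mathrm{reg}}$ with $\lambda_1 = 1$, $\lambda_2 = 10^{-3}$,
   minimized with Adam over the initial spot/gene embeddings (the encoder
   itself is parameter-free).  Every stage before the losses is linear, so
   gradients are assembled analytically in NumPy.
6. **Clustering** — K-means for single slices; a tied-covariance Gaussian
   mixture (the mclust EEE model family) on the concatenated embeddings for
   multi-slice data.  Agreement with annotations is scored by ARI/NMI,
   label-free quality by silhouette and Calinski–Harabasz.

## Worked example

```bash
python examples/single_slice_domains.py
```

```
slice: 500 spots x 200 genes
ARI = 1.000   (1.0 = clusters match the true domains exactly)
NMI = 1.000   (information shared with the true labels)
SC  = 0.835   (label-free embedding compactness, in [-1, 1])
final training loss = 590.7 (from 9952.0 at epoch 0)
```

The script simulates a 500-spot section with three layered domains
(negative-binomial counts, 30% dropout, 5-fold marker elevation), trains the
model and clusters the embeddings: ARI/NMI of 1.0 mean the recovered labels
coincide with the generating domains; the silhouette describes how compact
the domains are in embedding space without using the truth.

`examples/multi_slice_integration.py` runs the two-slice workflow (joint
ARI, per-slice scores, and the drop in slice-of-origin silhouette that shows
batch mixing), and `examples/ablation_comparison.py` compares the full model
with its no-contrastive and MLP-encoder ablations.

The same workflows are available from the shell:

```bash
hetspot simulate --seed 1 --out sim/
hetspot single sim/synth0_expr.csv --coords sim/synth0_coords.csv \
    --labels sim/synth0_labels.csv --clusters 3 --out result/
```

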