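"""End-to-end workflows: preprocess -> graphs -> encoder -> train -> cluster.

``run_single`` covers the one-slice workflow (intra-slice contrastive
triplets, K-means clustering); ``run_multi`` the multi-slice workflow
(shared-gene heterogeneous graph, CCA/MNN cross-slice anchors, tied-
covariance GMM clustering on the concatenated embeddings).  Both return a
:class:`PipelineResult` carrying embeddings, labels, metrics and the
training log, and both are deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict, field

import numpy as np

from . import cluster as cl
from . import contrastive as ct
from . import heterograph as hg
from . import io as hio
from . import training as tr
from .encoder import spatial_operator


@dataclass
class PipelineResult:
    embeddings: np.ndarray  # (N_total, d_emb) final spot embeddings
    labels: np.ndarray
    metrics: cl.MetricReport
    log: tr.TrainLog
    dataset: hio.MultiSliceDataset
    manifest: dict = field(default_factory=dict)


def _make_manifest(cfg: tr.TrainingConfig, dataset: hio.MultiSliceDataset, command: str) -> dict:
    h = hashlib.sha256()
    for s in dataset.slices:
        h.update(np.ascontiguousarray(s.raw_counts))
        h.update(np.ascontiguousarray(s.coords))
    return {
        "command": command,
        "config": asdict(cfg),
        "input_hash": h.hexdigest(),
        "seed": cfg.seed,
        "n_slices": dataset.n_slices,
        "n_spots": [s.n_spots for s in dataset.slices],
        "n_genes": len(dataset.gene_names),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _prepare(dataset: hio.MultiSliceDataset, cfg: tr.TrainingConfig):
    """Shared front half: preprocessing, both graphs, edge subgraphs, triplet inputs."""
    dataset = hio.preprocess(
        dataset, n_hvg=cfg.n_hvg, pca_d=cfg.pca_d, seed=cfg.seed
    )
    spatial_graphs = hio.build_spatial_graphs(dataset, k=cfg.spatial_k)
    A = spatial_operator(spatial_graphs, self_loop=cfg.self_loop)
    incidence = hg.binarize_edges([s.raw_counts for s in dataset.slices])
    graph = hg.assemble_adjacency(incidence)
    subgraphs = hg.sample_edge_subgraphs(
        graph, fraction=cfg.edge_fraction, seed=cfg.seed
    )
    return dataset, graph, A, subgraphs


def _intra_triplet_parts(dataset: hio.MultiSliceDataset, cfg: tr.TrainingConfig):
    positives, negatives = [], []
    for b, feats in enumerate(dataset.pca_embed):
        positives.append(ct.intra_slice_positives(feats, k_knn=cfg.k_knn))
        negatives.append(
            ct.louvain_negatives(
                feats, k_knn=cfg.k_knn, resolution=cfg.louvain_r,
                seed=cfg.seed + b,
            )
        )
    return positives, negatives


def _train(graph, A, subgraphs, dataset, triplets, cfg):
    norm_exprs = [s.norm_expr for s in dataset.slices]
    if cfg.ablate == "mlp":
        return tr.train_mlp_variant(graph, A, subgraphs, norm_exprs, triplets, cfg)
    return tr.train(graph, A, subgraphs, norm_exprs, triplets, cfg)


def run_single(
    dataset: hio.MultiSliceDataset, K: int, cfg: tr.TrainingConfig | None = None
) -> PipelineResult:
    """Single-slice workflow: intra-slice contrastive learning + K-means."""
    cfg = cfg or tr.TrainingConfig()
    if dataset.n_slices != 1:
        raise ValueError("run_single expects one slice; use run_multi")
    cfg.mode = "single"
    dataset, graph, A, subgraphs = _prepare(dataset, cfg)
    if cfg.ablate == "no-cl" or cfg.lambda1 == 0:
        triplets = None
    else:
        positives, negatives = _intra_triplet_parts(dataset, cfg)
        triplets = ct.build_triplets(
            positives, negatives, dataset.spot_offsets(), mode="single"
        )
    state, log = _train(graph, A, subgraphs, dataset, triplets, cfg)
    result = cl.cluster_kmeans(state.final_spot, K=K, seed=cfg.seed)
    metrics = _score(dataset, state.final_spot, result.labels)
    return PipelineResult(
        embeddings=state.final_spot,
        labels=result.labels,
        metrics=metrics,
        log=log,
        dataset=dataset,
        manifest=_make_manifest(cfg, dataset, "run_single"),
    )


def run_multi(
    dataset: hio.MultiSliceDataset,
    K: int,
    cfg: tr.TrainingConfig | None = None,
    groups: list[int] | None = None,
) -> PipelineResult:
    """Multi-slice workflow: CCA/MNN anchors + joint GMM clustering."""
    cfg = cfg or tr.TrainingConfig()
    if dataset.n_slices < 2:
        raise ValueError("run_multi expects >= 2 slices; use run_single")
    cfg.mode = "multi"
    dataset, graph, A, subgraphs = _prepare(dataset, cfg)
    if cfg.ablate == "no-cl" or cfg.lambda1 == 0:
        triplets = None
    else:
        positives, negatives = _intra_triplet_parts(dataset, cfg)
        mnn_plan = ct.plan_mnn_pairs([s.n_spots for s in dataset.slices], groups)
        mnn_pairs = []
        for b1, b2 in mnn_plan:
            pair = ct.cca_embed(
                dataset.pca_embed[b1], dataset.pca_embed[b2],
                seed=cfg.seed, slice_pair=(b1, b2),
            )
            pairs = ct.mutual_nearest_neighbors(pair.U1, pair.U2, k_mnn=cfg.k_mnn)
            mnn_pairs.append(((b1, b2), pairs))
        triplets = ct.build_triplets(
            positives, negatives, dataset.spot_offsets(),
            mnn_pairs=mnn_pairs, mode="multi",
        )
    state, log = _train(graph, A, subgraphs, dataset, triplets, cfg)
    result = cl.cluster_gmm_mclust(state.final_spot, K=K, seed=cfg.seed)
    metrics = _score(dataset, state.final_spot, result.labels)
    return PipelineResult(
        embeddings=state.final_spot,
        labels=result.labels,
        metrics=metrics,
        log=log,
        dataset=dataset,
        manifest=_make_manifest(cfg, dataset, "run_multi"),
    )


def _score(
    dataset: hio.MultiSliceDataset, embeddings: np.ndarray, labels: np.ndarray
) -> cl.MetricReport:
    report = cl.MetricReport()
    sc_, ch = cl.evaluate_unsupervised(embeddings, labels)
    report.sc, report.ch = sc_, ch
    truths = [s.labels for s in dataset.slices]
    if all(t is not None for t in truths):
        truth = np.concatenate([np.asarray(t) for t in truths])
        report.ari, report.nmi = cl.evaluate_supervised(labels, truth)
        per_slice = {}
        offsets = dataset.spot_offsets()
        for o, s in zip(offsets, dataset.slices):
            sl = slice(int(o), int(o) + s.n_spots)
            ari, nmi = cl.evaluate_supervised(labels[sl], np.asarray(s.labels))
            per_slice[s.slice_id] = {"ari": ari, "nmi": nmi}
        report.per_slice = per_slice
    return report


def save_result(result: PipelineResult, out_dir) -> None:
    """Write h5ad, labels TSV, metrics JSON and the run manifest."""
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata = hio.to_anndata(result.dataset, embeddings=result.embeddings, labels=result.labels)
    adata.write_h5ad(out / "result.h5ad")
    rows = []
    offsets = result.dataset.spot_offsets()
    for o, s in zip(offsets, result.dataset.slices):
        for i, name in enumerate(s.spot_names):
            rows.append((name, s.slice_id, int(result.labels[int(o) + i])))
    pd.DataFrame(rows, columns=["spot_name", "slice_id", "cluster"]).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    metrics = {
        k: (None if v is None or (isinstance(v, float) and v != v) else v)
        for k, v in asdict(result.metrics).items()
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    pd.DataFrame(
        {
            "epoch": range(len(result.log.total)),
            "mse": result.log.mse,
            "cl": result.log.cl,
            "reg": result.log.reg,
            "total": result.log.total,
        }
    ).to_csv(out / "train_log.csv", index=False)
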