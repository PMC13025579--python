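"""Clustering of spot embeddings and evaluation metrics.

Single-slice runs use K-means (sparse spot counts favour its stability);
multi-slice runs use a tied-covariance Gaussian mixture — the model family of
mclust's EEE parameterization — fitted jointly on the concatenated
embeddings.  Supervised agreement is scored with ARI and NMI; label-free
quality with the silhouette coefficient and the Calinski-Harabasz index, both
reported as missing (NaN) for degenerate single-cluster partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.mixture import GaussianMixture


@dataclass
class ClusterResult:
    labels: np.ndarray
    n_clusters: int
    method: str
    seed: int


@dataclass
class MetricReport:
    ari: float | None = None
    nmi: float | None = None
    sc: float | None = None
    ch: float | None = None
    per_slice: dict | None = None


def cluster_kmeans(embeddings: np.ndarray, K: int, seed: int = 0) -> ClusterResult:
    """Seeded k-means++ with 10 restarts, best inertia kept."""
    n = embeddings.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds {n} spots")
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(embeddings)
    return ClusterResult(labels=labels, n_clusters=K, method="kmeans", seed=seed)


def cluster_gmm_mclust(
    embeddings: np.ndarray, K: int, seed: int = 0, max_iter: int = 200
) -> ClusterResult:
    """Tied-covariance Gaussian mixture (EEE-style) from a k-means start.

    All components share one full covariance matrix; assignment is by
    maximum posterior.  Non-convergence after ``max_iter`` EM iterations
    warns and returns the best-so-far fit.
    """
    n = embeddings.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds {n} spots")
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
    km_labels = km.fit_predict(embeddings)
    gmm = GaussianMixture(
        n_components=K,
        covariance_type="tied",
        means_init=km.cluster_centers_,
        random_state=seed,
        max_iter=max_iter,
        reg_covar=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            labels = gmm.fit_predict(embeddings)
        except ValueError:
            warnings.warn("GMM fit failed; falling back to the k-means labels")
            labels = km_labels
    if hasattr(gmm, "converged_") and not gmm.converged_:
        warnings.warn("GMM EM did not converge; returning best-so-far fit")
    return ClusterResult(labels=labels, n_clusters=K, method="gmm_mclust", seed=seed)


def evaluate_supervised(
    pred: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """ARI and NMI (arithmetic-mean normalization) over spots with known truth.

    Spots whose truth is missing (None/NaN) are excluded from both labelings.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth cover different spot sets")
    mask = np.array([t is not None and t == t for t in truth])
    if not mask.any():
        raise ValueError("no spots with ground-truth labels")
    p = pred[mask]
    t = np.asarray([str(x) for x in truth[mask]])
    return (
        float(adjusted_rand_score(t, p)),
        float(normalized_mutual_info_score(t, p, average_method="arithmetic")),
    )


def evaluate_unsupervised(
    embeddings: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Silhouette and Calinski-Harabasz; NaN for single-cluster partitions."""
    if len(np.unique(labels)) < 2:
        return float("nan"), float("nan")
    return (
        float(silhouette_score(embeddings, labels, metric="euclidean")),
        float(calinski_harabasz_score(embeddings, labels)),
    )


def rank_methods(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank a methods x datasets table of higher-is-better scores.

    Rank 1 is the best per dataset (column); ties get the average rank;
    missing scores stay NA and are effectively ranked last.
    """
    ranks = scores.rank(axis=0, ascending=False, method="average", na_option="keep")
    ranks["mean_rank"] = ranks.mean(axis=1, skipna=True)
    return ranks
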