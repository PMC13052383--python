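"""Fuse k-means and DBSCAN views of the learned feature space into the
final event correlation matrix.

The k-means view scores co-clustered pairs by relative centroid-scaled
distance; the DBSCAN view scores them by hop count on the
eps-neighborhood graph.  Pairs co-clustered by neither view carry exactly
zero correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import silhouette_score

from care_et.event_model import CorrelationMatrix, EventFeatureMatrix, ValidationError

__all__ = [
    "ClusteringResult",
    "select_k",
    "kmeans_correlation",
    "dbscan_correlation",
    "fuse_correlations",
    "compute_relevance",
    "default_eps",
]

log = logging.getLogger(__name__)

_FLOOR = 1e-12


@dataclass
class ClusteringResult:
    kmeans_labels: np.ndarray
    kmeans_centroids: np.ndarray
    dbscan_labels: np.ndarray
    chosen_k: int

    def __post_init__(self) -> None:
        if self.chosen_k < 2:
            raise ValidationError("chosen_k must be >= 2")
        if len(self.kmeans_labels) != len(self.dbscan_labels):
            raise ValidationError("label vectors differ in length")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, EventFeatureMatrix):
        return features.matrix
    return np.asarray(features, dtype=float)


def select_k(features, k_range, seed: int = 0) -> int:
    """Pick k maximizing mean silhouette; break ties by the elbow
    criterion (largest second difference of within-cluster SSE), then by
    the smaller k."""
    X = _as_matrix(features)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples to select k")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValidationError("k_range contains no feasible k")
    if np.allclose(X, X[0]):
        warnings.warn("constant features: k selection is degenerate, returning 2")
        return 2

    sil: dict[int, float] = {}
    sse: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        sse[k] = float(km.inertia_)
        if len(set(km.labels_)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, km.labels_))
    best = max(sil.values())
    tied = sorted(k for k in ks if abs(sil[k] - best) < 1e-12)
    if len(tied) == 1:
        return tied[0]
    # elbow: largest second difference of SSE over the tied candidates
    elbow: dict[int, float] = {}
    for k in tied:
        if k - 1 in sse and k + 1 in sse:
            elbow[k] = sse[k - 1] - 2 * sse[k] + sse[k + 1]
        else:
            elbow[k] = -np.inf
    best_elbow = max(elbow.values())
    return min(k for k in tied if elbow[k] == best_elbow)


def kmeans_correlation(
    features, k: int, seed: int = 0, return_result: bool = False
):
    """Centroid-view correlation.

    For i, j in the same cluster: 1 - ||h_i - h_j|| / (2 * r_c) with r_c
    the largest member-to-centroid distance in that cluster (floored);
    different clusters score 0; diagonal 1; clipped to [0, 1].
    """
    X = _as_matrix(features)
    n = X.shape[0]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    labels = km.labels_
    if len(set(labels)) < k:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + 1).fit(X)
        labels = km.labels_
        if len(set(labels)) < k:
            raise ValidationError(f"empty cluster for k={k} after re-seeding")
    centroids = km.cluster_centers_
    radius = {}
    for c in range(k):
        members = X[labels == c]
        radius[c] = max(
            float(np.max(np.linalg.norm(members - centroids[c], axis=1))), _FLOOR
        )
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                C[i, j] = 1.0
            elif labels[i] == labels[j]:
                d = np.linalg.norm(X[i] - X[j])
                C[i, j] = np.clip(1.0 - d / (2.0 * radius[labels[i]]), 0.0, 1.0)
    if return_result:
        return C, labels, centroids
    return C


def default_eps(features) -> float:
    """Half the median pairwise distance (shipped DBSCAN default)."""
    X = _as_matrix(features)
    n = X.shape[0]
    if n < 2:
        return 1.0
    dists = [
        np.linalg.norm(X[i] - X[j]) for i in range(n) for j in range(i + 1, n)
    ]
    med = float(np.median(dists))
    return max(med * 0.5, _FLOOR)


def dbscan_correlation(
    features, eps: float | None = None, min_pts: int = 4, return_labels: bool = False
):
    """Density-view correlation: 1 / (1 + hops) along shortest paths of
    the eps-neighborhood graph for same-cluster pairs; noise points and
    cross-cluster pairs score 0; diagonal 1."""
    X = _as_matrix(features)
    n = X.shape[0]
    if eps is None:
        eps = default_eps(X)
    if eps <= 0:
        raise ValidationError("eps must be positive")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(X).labels_

    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        if labels[i] == -1:
            continue
        for j in range(i + 1, n):
            if labels[j] == -1:
                continue
            if np.linalg.norm(X[i] - X[j]) <= eps:
                G.add_edge(i, j)

    C = np.zeros((n, n))
    np.fill_diagonal(C, 1.0)
    for i in range(n):
        if labels[i] == -1:
            continue
        hops = nx.single_source_shortest_path_length(G, i)
        for j, h in hops.items():
            if j != i and labels[j] == labels[i]:
                C[i, j] = 1.0 / (1.0 + h)
    if return_labels:
        return C, labels
    return C


def fuse_correlations(
    C_km: np.ndarray,
    C_db: np.ndarray,
    weight: float = 0.5,
    event_ids: list[str] | None = None,
) -> CorrelationMatrix:
    """Weighted fusion Rel = weight*C_km + (1-weight)*C_db.

    When one view assigns zero everywhere off the diagonal (e.g. a fully
    noise DBSCAN run), the fusion falls back to the other view alone.
    """
    C_km = np.asarray(C_km, dtype=float)
    C_db = np.asarray(C_db, dtype=float)
    if C_km.shape != C_db.shape:
        raise ValidationError("correlation shapes differ")
    if not 0.0 <= weight <= 1.0:
        raise ValidationError("weight must lie in [0, 1]")
    n = C_km.shape[0]
    off = ~np.eye(n, dtype=bool)
    if n > 1 and not np.any(C_db[off]) and np.any(C_km[off]):
        log.warning("density view is all-zero; falling back to centroid view")
        fused = C_km.copy()
    elif n > 1 and not np.any(C_km[off]) and np.any(C_db[off]):
        log.warning("centroid view is all-zero; falling back to density view")
        fused = C_db.copy()
    else:
        fused = weight * C_km + (1.0 - weight) * C_db
    ids = event_ids if event_ids is not None else [f"ev-{i:06d}" for i in range(n)]
    return CorrelationMatrix(ids, fused)


def compute_relevance(
    features: EventFeatureMatrix,
    k: int | None = None,
    eps: float | None = None,
    min_pts: int = 4,
    weight: float = 0.5,
    seed: int = 0,
) -> tuple[CorrelationMatrix, ClusteringResult]:
    """End-to-end joint adjustment: choose k if unset, run both views,
    fuse."""
    X = features.matrix
    if k is None:
        k = select_k(X, range(2, max(3, min(9, X.shape[0] - 1))), seed=seed)
    C_km, km_labels, centroids = kmeans_correlation(X, k, seed=seed, return_result=True)
    C_db, db_labels = dbscan_correlation(X, eps=eps, min_pts=min_pts, return_labels=True)
    rel = fuse_correlations(C_km, C_db, weight=weight, event_ids=features.event_ids)
    result = ClusteringResult(
        kmeans_labels=km_labels,
        kmeans_centroids=centroids,
        dbscan_labels=db_labels,
        chosen_k=k,
    )
    return rel, result
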