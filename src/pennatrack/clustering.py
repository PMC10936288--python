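"""Pixel clustering: DBSCAN (default), K-means and single-linkage HAC.

Clustering operates on (col, row) coordinates only; pixel intensity has
already been used by the denoising threshold and re-enters later through the
cluster value function. Distances are Euclidean.

Determinism: pixels are processed in row-major scan order (row, then col),
and DBSCAN border points reachable from several clusters are claimed by the
first-discovered cluster under that order. ``brute_force_components`` is an
O(N²) literal implementation of the same density-connectivity definition and
serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import PixelSet

__all__ = [
    "ClusterParams",
    "Cluster",
    "cluster_dbscan",
    "cluster_kmeans",
    "cluster_hac",
    "brute_force_components",
    "cluster_pixels",
]


@dataclass
class ClusterParams:
    method: str = "dbscan"
    eps: float = 2.0
    min_pts: int = 5
    k: int | None = None  # kmeans; None -> match DBSCAN cluster count
    max_iter: int = 300
    seed: int = 0
    link_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.link_threshold <= 0:
            raise ValueError("eps and link_threshold must be > 0")
        if self.min_pts < 1 or (self.k is not None and self.k < 1):
            raise ValueError("min_pts and k must be >= 1")
        if self.method not in {"dbscan", "kmeans", "hac"}:
            raise ValueError(f"unknown clustering method {self.method!r}")


@dataclass
class Cluster:
    """A group of foreground pixels from one ROI."""

    id: int
    members: PixelSet

    def __len__(self) -> int:
        return len(self.members)


def _scan_order(px: PixelSet) -> np.ndarray:
    """Row-major processing order (row, then col)."""
    return np.lexsort((px.cols, px.rows))


def _subset(px: PixelSet, idx: np.ndarray) -> PixelSet:
    return PixelSet(px.cols[idx], px.rows[idx], px.intensities[idx], px.origin_roi)


def _labels_to_clusters(px: PixelSet, labels: np.ndarray) -> tuple[list[Cluster], PixelSet]:
    clusters = []
    for cid in range(labels.max() + 1 if len(labels) else 0):
        idx = np.flatnonzero(labels == cid)
        if len(idx):
            clusters.append(Cluster(len(clusters), _subset(px, idx)))
    noise = _subset(px, np.flatnonzero(labels == -1))
    return clusters, noise


def cluster_dbscan(px: PixelSet, eps: float, min_pts: int) -> tuple[list[Cluster], PixelSet]:
    """Density-based clustering of the pixel set.

    A pixel is a core point when at least ``min_pts`` pixels (itself included)
    lie within ``eps`` of it; clusters are the sets of pixels reachable from a
    core point through chains of core points; the rest is noise.
    """
    n = len(px)
    if n == 0:
        return [], PixelSet.empty(px.origin_roi)
    order = _scan_order(px)
    coords = px.coords()
    tree = cKDTree(coords)
    neigh = tree.query_ball_point(coords, eps)  # includes self
    core = np.array([len(nb) >= min_pts for nb in neigh])

    labels = np.full(n, -1, dtype=np.int64)
    cid = -1
    for seed in order:
        if not core[seed] or labels[seed] != -1:
            continue
        cid += 1
        labels[seed] = cid
        queue = [seed]
        while queue:
            i = queue.pop()
            for j in neigh[i]:
                if labels[j] == -1:
                    labels[j] = cid
                    if core[j]:
                        queue.append(j)
    return _labels_to_clusters(px, labels)


def brute_force_components(
    px: PixelSet, eps: float, min_pts: int
) -> tuple[list[Cluster], PixelSet]:
    """O(N²) literal implementation of the density-connectivity definition.

    Core points are found from the full pairwise distance matrix; clusters are
    the connected components of the core-point graph plus the non-core points
    within ``eps`` of a component's core; border points shared between
    components go to the component whose earliest core point comes first in
    row-major scan order. Reference oracle for :func:`cluster_dbscan`.
    """
    n = len(px)
    if n == 0:
        return [], PixelSet.empty(px.origin_roi)
    coords = px.coords()
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    within = d2 <= eps * eps
    core = within.sum(axis=1) >= min_pts  # diagonal counts the point itself

    # connected components of the core graph, by repeated expansion
    comp = np.full(n, -1, dtype=np.int64)
    ncomp = 0
    for i in range(n):
        if core[i] and comp[i] == -1:
            members = np.zeros(n, dtype=bool)
            members[i] = True
            while True:
                grown = members | (within[:, members].any(axis=1) & core)
                if (grown == members).all():
                    break
                members = grown
            comp[members] = ncomp
            ncomp += 1

    # rank components by earliest core point in row-major order
    scan_rank = np.empty(n, dtype=np.int64)
    scan_rank[_scan_order(px)] = np.arange(n)
    first = [scan_rank[(comp == c) & core].min() for c in range(ncomp)]
    relabel = np.argsort(np.argsort(first))

    labels = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if core[i]:
            labels[i] = relabel[comp[i]]
        else:
            owners = comp[within[i] & core]
            if len(owners):
                labels[i] = relabel[owners].min()
    return _labels_to_clusters(px, labels)


def cluster_kmeans(
    px: PixelSet, k: int, max_iter: int = 300, seed: int = 0
) -> list[Cluster]:
    """Partition the pixel coordinates into ``k`` clusters by minimizing the
    within-cluster sum of squares (Lloyd iterations, seeded initialization)."""
    from sklearn.cluster import KMeans

    if len(px) < k:
        raise ValueError(f"need at least k={k} pixels, got {len(px)}")
    km = KMeans(n_clusters=k, n_init=4, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(px.coords())
    clusters = []
    for cid in range(k):
        idx = np.flatnonzero(labels == cid)
        if len(idx):  # empty clusters are dropped
            clusters.append(Cluster(len(clusters), _subset(px, idx)))
    return clusters


def kmeans_wcss(px: PixelSet, clusters: list[Cluster]) -> float:
    """Within-cluster sum of squares of a given partition."""
    total = 0.0
    for c in clusters:
        xy = c.members.coords()
        total += float(((xy - xy.mean(axis=0)) ** 2).sum())
    return total


def cluster_hac(px: PixelSet, link_threshold: float) -> list[Cluster]:
    """Single-linkage agglomeration: clusters are the connected components of
    the graph joining pixel pairs at Euclidean distance strictly below
    ``link_threshold``."""
    n = len(px)
    if n == 0:
        return []
    coords = px.coords()
    tree = cKDTree(coords)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(link_threshold, output_type="ndarray"):
        if ((coords[i] - coords[j]) ** 2).sum() < link_threshold**2:  # strict
            parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(n)])
    labels = np.full(n, -1, dtype=np.int64)
    cid = -1
    for i in _scan_order(px):
        if labels[i] == -1:
            cid += 1
            labels[roots == roots[i]] = cid
    clusters, _ = _labels_to_clusters(px, labels)
    return clusters


def cluster_pixels(px: PixelSet, params: ClusterParams) -> tuple[list[Cluster], PixelSet]:
    """Dispatch to the configured clustering method.

    For K-means without an explicit ``k``, the number of DBSCAN clusters found
    on the same input is used, so method comparisons run without per-frame
    hand tuning. K-means and HAC produce no noise set.
    """
    if params.method == "dbscan":
        return cluster_dbscan(px, params.eps, params.min_pts)
    if params.method == "hac":
        return cluster_hac(px, params.link_threshold), PixelSet.empty(px.origin_roi)
    k = params.k
    if k is None:
        k = max(1, len(cluster_dbscan(px, params.eps, params.min_pts)[0]))
    if len(px) < k:
        return [], _subset(px, np.arange(len(px)))
    return (
        cluster_kmeans(px, k, params.max_iter, params.seed),
        PixelSet.empty(px.origin_roi),
    )
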