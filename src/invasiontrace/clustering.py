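"""Cluster-number selection and territory partition.

Observation points are partitioned with K-means (Lloyd iterations, best of
several k-means++ restarts); the number of clusters is chosen by maximising
the mean silhouette width over a scan of k; the territory is partitioned by
nearest-centroid (Voronoi) assignment.  These are the pre-processing steps
applied before per-cluster geographic profiling: a multi-origin invasion
shows up as distinct clusters of first records, each profiled separately.

Distances default to Euclidean on raw lon/lat degrees, mirroring the
coordinate-CSV workflow of the original analysis scripts; great-circle
distance in kilometres is available via ``metric="haversine_km"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .distances import pairwise_distances

__all__ = [
    "ClusterPartition",
    "VoronoiPartition",
    "kmeans_partition",
    "silhouette",
    "select_k",
    "voronoi_assign",
    "voronoi_polygons",
]


@dataclass
class ClusterPartition:
    """Assignment of points to k clusters with silhouette diagnostics."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    per_point_silhouette: np.ndarray
    mean_silhouette: float
    seed: int
    n_restarts: int
    inertia: float  # within-cluster sum of squares

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class VoronoiPartition:
    """Nearest-site partition: ``cell_of[i]`` is the site index of query i."""

    sites: np.ndarray
    cell_of: np.ndarray
    metric: str = "euclidean_degrees"
    polygons: list | None = field(default=None, repr=False)


def kmeans_partition(points, k: int, seed: int = 0, n_restarts: int = 20) -> ClusterPartition:
    """K-means partition of (n, 2) points into k clusters, best of `n_restarts`.

    Lloyd iterations to convergence (max 300), k-means++ seeding, deterministic
    for a fixed seed.  Silhouette values are attached when 2 <= k < n, else
    set to NaN (they are undefined for a single cluster).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 1:
        raise ValueError("at least one point required")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, n={n}]")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=300,
        tol=0.0,
        algorithm="lloyd",
        random_state=int(seed),
    ).fit(pts)
    labels = km.labels_.astype(int)
    if 2 <= k and len(np.unique(labels)) >= 2:
        sil, mean_sil = silhouette(pts, labels)
    else:
        sil = np.full(n, np.nan)
        mean_sil = float("nan")
    return ClusterPartition(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_.copy(),
        per_point_silhouette=sil,
        mean_silhouette=mean_sil,
        seed=int(seed),
        n_restarts=int(n_restarts),
        inertia=float(km.inertia_),
    )


def silhouette(points, labels, metric: str = "euclidean_degrees"):
    """Per-point silhouette widths s(i) = (b - a) / max(a, b) and their mean.

    a(i) is the mean distance to the other members of i's cluster; b(i) the
    smallest mean distance to any other cluster.  Points in singleton
    clusters get s = 0 by convention.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = pairwise_distances(pts, pts, metric)
    n = len(pts)
    per_point = np.zeros(n)
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            continue  # singleton convention: s = 0
        a = d[i, labels == own].sum() / (sizes[own] - 1)  # excludes d(i,i)=0
        b = min(d[i, labels == c].mean() for c in uniq if c != own)
        per_point[i] = (b - a) / max(a, b)
    return per_point, float(np.mean(per_point))


def select_k(
    points,
    k_min: int = 2,
    k_max: int | None = None,
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Scan k in [k_min, k_max], return the silhouette-optimal k and the profile.

    For each k, the best-of-restarts K-means partition is scored by mean
    silhouette; k* maximises it, ties broken in favour of the smaller k
    (parsimony).  The full profile (k, mean_silhouette) is returned for
    plotting, the analogue of the published silhouette scans.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to compare cluster numbers")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max is None:
        k_max = min(8, n - 1)
    if k_max > n - 1:
        raise ValueError(f"k_max={k_max} must be <= n-1={n - 1}")
    rows = []
    best_k, best_sil = None, -np.inf
    for k in range(k_min, k_max + 1):
        part = kmeans_partition(pts, k, seed=seed, n_restarts=n_restarts)
        rows.append({"k": k, "mean_silhouette": part.mean_silhouette, "wcss": part.inertia})
        if part.mean_silhouette > best_sil:  # strict: ties keep the smaller k
            best_sil, best_k = part.mean_silhouette, k
    return best_k, pd.DataFrame(rows)


def voronoi_assign(sites, queries, metric: str = "euclidean_degrees") -> VoronoiPartition:
    """Assign each query point to its nearest site; ties go to the lowest index."""
    sites = np.asarray(sites, dtype=float).reshape(-1, 2)
    if len(sites) < 1:
        raise ValueError("at least one site required")
    queries = np.asarray(queries, dtype=float).reshape(-1, 2)
    d = pairwise_distances(queries, sites, metric)
    return VoronoiPartition(sites=sites, cell_of=np.argmin(d, axis=1), metric=metric)


def voronoi_polygons(sites, extent) -> list:
    """Planar Voronoi cell polygons clipped to `extent`, ordered by site index.

    extent = (lon_min, lon_max, lat_min, lat_max).  Uses a planar
    approximation in degrees (adequate at Mediterranean scale for display);
    cell *assignment* via :func:`voronoi_assign` is the authoritative
    partition.
    """
    from shapely.geometry import MultiPoint, Point, box
    from shapely.ops import voronoi_diagram

    sites = np.asarray(sites, dtype=float).reshape(-1, 2)
    lon_min, lon_max, lat_min, lat_max = extent
    bbox = box(lon_min, lat_min, lon_max, lat_max)
    if len(sites) == 1:
        return [bbox]
    cells = voronoi_diagram(MultiPoint([tuple(s) for s in sites]), envelope=bbox)
    out = [None] * len(sites)
    for cell in cells.geoms:
        clipped = cell.intersection(bbox)
        # match each raw cell back to the site it contains
        for i, s in enumerate(sites):
            if out[i] is None and cell.contains(Point(*s)):
                out[i] = clipped
                break
    # degenerate clips (site on the boundary) fall back to nearest assignment
    for i, cell in enumerate(out):
        if cell is None:
            out[i] = bbox.intersection(Point(*sites[i]).buffer(1e-9))
    return out
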