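"""Rossmo criminal-geographic-targeting surfaces for invasion-origin inference.

Geographic profiling treats a set of linked spatial events — here, the
first records of an invasive plant within one cluster — as clues to a
common anchor point, the probable introduction area.  Each grid cell j is
scored against every observation i at distance d_ij:

    score_j = sum_i [ 1{d_ij > B} * d_ij^(-f)
                    + 1{d_ij <= B} * B^(g-f) * (2B - d_ij)^(-g) ]

Outside the buffer radius B the score decays as a power law in distance
(events are unlikely far from the origin); inside B it *rises* towards the
ring d = B (the classic buffer-zone behaviour: events tend not to sit
exactly on top of the anchor).  With f = g the single-observation surface
is continuous at d = B and maximal on that ring.  The summed surface is
normalised to unit mass and read as a relative origin-probability map; its
top-q mass region is the analogue of the published "red areas".

The hit score — the fraction of the study area scored at or above the cell
holding the true origin — is the standard evaluation of how efficiently a
geoprofile would prioritise a search; it is computable only in simulation,
where the origin is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distances import haversine_km, pairwise_distances
from .records import RecordSet, filter_until, first_records

__all__ = [
    "GeoprofileParams",
    "Geoprofile",
    "OriginEstimate",
    "ClusterGeoprofile",
    "rossmo_surface",
    "estimate_origin",
    "hit_score",
    "origin_in_top_region",
    "cluster_geoprofiles",
]


@dataclass(frozen=True)
class GeoprofileParams:
    """Tunables of the Rossmo surface.

    buffer_b : float or "auto"
        Buffer radius, in the units of `distance_metric` (km for
        haversine).  "auto" sets B to half the mean nearest-neighbour
        distance among the cluster's observations, making the buffer
        data-adaptive; a single observation falls back to 10% of the grid
        diagonal.
    exponent_f, exponent_g : float
        Decay exponents outside/inside the buffer.  f = g = 1.2 keeps the
        surface continuous at d = B.
    grid_nx, grid_ny : int
        Grid resolution (cells along lon / lat).
    padding_fraction : float
        Extent padding beyond the observation bounding box, per side, as a
        fraction of the box span.
    epsilon_d : float or None
        Distance clamp guarding the d -> 0 and d -> 2B singularities; None
        means half the grid-cell diagonal (computed per surface).
    """

    buffer_b: float | str = "auto"
    exponent_f: float = 1.2
    exponent_g: float = 1.2
    grid_nx: int = 200
    grid_ny: int = 200
    padding_fraction: float = 0.10
    distance_metric: str = "haversine_km"
    epsilon_d: float | None = None

    def __post_init__(self):
        if self.buffer_b != "auto" and not float(self.buffer_b) > 0:
            raise ValueError("buffer_b must be positive or 'auto'")
        if self.exponent_f <= 0 or self.exponent_g <= 0:
            raise ValueError("exponents must be positive")
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid must be at least 2x2")
        if self.padding_fraction < 0:
            raise ValueError("padding_fraction must be >= 0")
        if self.distance_metric not in ("haversine_km", "euclidean_degrees"):
            raise ValueError(f"unknown metric {self.distance_metric!r}")


@dataclass
class Geoprofile:
    """Normalised origin-probability surface on a regular lon/lat grid.

    ``scores`` is (grid_ny, grid_nx), row i spanning latitude ``lats[i]``,
    column j longitude ``lons[j]``; scores are non-negative and sum to 1.
    ``raw_scores`` keeps the pre-normalisation sum over observations (the
    surface is additive in the observations, which the tests exploit).
    """

    extent: tuple[float, float, float, float]
    scores: np.ndarray
    raw_scores: np.ndarray
    params: GeoprofileParams
    buffer_used: float
    epsilon_used: float
    cluster_id: int | None = None

    @property
    def lons(self) -> np.ndarray:
        lon_min, lon_max, _, _ = self.extent
        return _cell_centers(lon_min, lon_max, self.params.grid_nx)

    @property
    def lats(self) -> np.ndarray:
        _, _, lat_min, lat_max = self.extent
        return _cell_centers(lat_min, lat_max, self.params.grid_ny)

    @property
    def peak_lonlat(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(int(np.argmax(self.scores)), self.scores.shape)
        return float(self.lons[ix]), float(self.lats[iy])

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside extent."""
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            raise ValueError(f"point ({lon}, {lat}) outside extent {self.extent}")
        nx, ny = self.params.grid_nx, self.params.grid_ny
        ix = min(int((lon - lon_min) / (lon_max - lon_min) * nx), nx - 1)
        iy = min(int((lat - lat_min) / (lat_max - lat_min) * ny), ny - 1)
        return iy, ix

    def to_long_dataframe(self):
        import pandas as pd

        lon_grid, lat_grid = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {"lon": lon_grid.ravel(), "lat": lat_grid.ravel(), "score": self.scores.ravel()}
        )

    def write_asc(self, path: str | Path) -> None:
        """ESRI ASCII grid export (cellsize from the lon axis; row 1 = north)."""
        lon_min, lon_max, lat_min, _ = self.extent
        cellsize = (lon_max - lon_min) / self.params.grid_nx
        header = (
            f"ncols {self.params.grid_nx}\n"
            f"nrows {self.params.grid_ny}\n"
            f"xllcorner {lon_min:.10g}\n"
            f"yllcorner {lat_min:.10g}\n"
            f"cellsize {cellsize:.10g}\n"
            f"NODATA_value -9999\n"
        )
        body = "\n".join(
            " ".join(f"{v:.8e}" for v in row) for row in self.scores[::-1]
        )
        Path(path).write_text(header + body + "\n", encoding="utf-8")


@dataclass
class OriginEstimate:
    """Peak cell and top-q probability-mass region of a geoprofile."""

    peak_lonlat: tuple[float, float]
    top_region: np.ndarray  # boolean (ny, nx) mask
    q: float
    mass: float  # actual mass covered (>= q)

    @property
    def n_cells(self) -> int:
        return int(self.top_region.sum())


@dataclass
class ClusterGeoprofile:
    cluster_id: int
    points: np.ndarray
    geoprofile: Geoprofile
    origin: OriginEstimate


def _cell_centers(lo: float, hi: float, n: int) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _auto_extent(pts: np.ndarray, padding: float) -> tuple[float, float, float, float]:
    lon_min, lat_min = pts.min(axis=0)
    lon_max, lat_max = pts.max(axis=0)
    span_lon = max(lon_max - lon_min, 1e-6)
    span_lat = max(lat_max - lat_min, 1e-6)
    # degenerate (single point / collinear) boxes get a minimum span so the
    # grid always has area
    pad_lon = padding * span_lon + (0.5 if span_lon < 0.5 else 0.0)
    pad_lat = padding * span_lat + (0.5 if span_lat < 0.5 else 0.0)
    return (
        lon_min - pad_lon,
        lon_max + pad_lon,
        max(lat_min - pad_lat, -90.0),
        min(lat_max + pad_lat, 90.0),
    )


def _auto_buffer(pts: np.ndarray, metric: str, extent, params) -> float:
    if len(pts) >= 2:
        d = pairwise_distances(pts, pts, metric)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        b = 0.5 * float(nn.mean())
        if b > 0:
            return b
    # single observation (or all coincident): no NN scale; use 10% of the
    # grid diagonal so the ring sits well inside the extent
    lon_min, lon_max, lat_min, lat_max = extent
    if metric == "haversine_km":
        diag = float(haversine_km((lon_min, lat_min), (lon_max, lat_max)))
    else:
        diag = float(np.hypot(lon_max - lon_min, lat_max - lat_min))
    return 0.10 * diag


def _cell_diagonal(extent, params) -> float:
    lon_min, lon_max, lat_min, lat_max = extent
    dx = (lon_max - lon_min) / params.grid_nx
    dy = (lat_max - lat_min) / params.grid_ny
    if params.distance_metric == "haversine_km":
        lat_mid = 0.5 * (lat_min + lat_max)
        return float(
            haversine_km((0.0, lat_mid - dy / 2), (dx, lat_mid + dy / 2))
        )
    return float(np.hypot(dx, dy))


def rossmo_surface(
    points,
    params: GeoprofileParams | None = None,
    extent: tuple[float, float, float, float] | None = None,
    cluster_id: int | None = None,
) -> Geoprofile:
    """Compute the normalised Rossmo surface for a set of observations.

    The grid covers the observation bounding box plus padding (or an
    explicit `extent`).  Distances are clamped below at ``epsilon_d`` and,
    inside the buffer, away from 2B by the same epsilon, keeping the
    surface finite everywhere.
    """
    params = params or GeoprofileParams()
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("at least one observation required")
    if extent is None:
        extent = _auto_extent(pts, params.padding_fraction)

    b = _auto_buffer(pts, params.distance_metric, extent, params) if params.buffer_b == "auto" else float(params.buffer_b)
    eps = _cell_diagonal(extent, params) / 2.0 if params.epsilon_d is None else float(params.epsilon_d)
    eps = min(eps, 0.5 * b)  # clamp must never push a distance past the buffer ring

    lons = _cell_centers(extent[0], extent[1], params.grid_nx)
    lats = _cell_centers(extent[2], extent[3], params.grid_ny)
    lon_grid, lat_grid = np.meshgrid(lons, lats)
    cells = np.column_stack([lon_grid.ravel(), lat_grid.ravel()])

    d = pairwise_distances(pts, cells, params.distance_metric)  # (n_obs, n_cells)
    d = np.maximum(d, eps)
    f, g = params.exponent_f, params.exponent_g
    outside = d > b
    far = d ** (-f)
    near = (b ** (g - f)) * np.maximum(2.0 * b - d, eps) ** (-g)
    raw = np.where(outside, far, near).sum(axis=0).reshape(params.grid_ny, params.grid_nx)

    total = raw.sum()
    return Geoprofile(
        extent=tuple(extent),
        scores=raw / total,
        raw_scores=raw,
        params=params,
        buffer_used=b,
        epsilon_used=eps,
        cluster_id=cluster_id,
    )


def estimate_origin(gp: Geoprofile, q: float = 0.05) -> OriginEstimate:
    """Peak cell and the smallest set of top cells holding >= q of the mass."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    flat = gp.scores.ravel()
    order = np.argsort(-flat, kind="stable")  # stable: ties in row-major order
    csum = np.cumsum(flat[order])
    n_top = int(np.searchsorted(csum, q - 1e-12) + 1)
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:n_top]] = True
    return OriginEstimate(
        peak_lonlat=gp.peak_lonlat,
        top_region=mask.reshape(gp.scores.shape),
        q=float(q),
        mass=float(csum[n_top - 1]),
    )


def hit_score(gp: Geoprofile, true_origin) -> float:
    """Fraction of cells scored at or above the cell holding the true origin.

    1/(nx*ny) is the best attainable value (origin in the unique top cell);
    1.0 means the surface carries no localisation signal.
    """
    lon, lat = float(true_origin[0]), float(true_origin[1])
    iy, ix = gp.cell_index(lon, lat)
    threshold = gp.scores[iy, ix]
    return float(np.count_nonzero(gp.scores >= threshold) / gp.scores.size)


def origin_in_top_region(est: OriginEstimate, gp: Geoprofile, true_origin) -> bool:
    """Whether the true origin's cell belongs to the estimate's top-q region."""
    iy, ix = gp.cell_index(float(true_origin[0]), float(true_origin[1]))
    return bool(est.top_region[iy, ix])


def cluster_geoprofiles(
    rs: RecordSet,
    cutoff: int | None = None,
    k_range: tuple[int, int | None] = (2, None),
    seed: int = 0,
    n_restarts: int = 20,
    gp_params: GeoprofileParams | None = None,
    q: float = 0.05,
    k: int | None = None,
):
    """Full per-cluster profiling: filter → first records → select k → K-means → Rossmo.

    Returns (partition, silhouette_profile, [ClusterGeoprofile ...]) in
    cluster-index order.  `k` forces the cluster number, bypassing the
    silhouette scan.
    """
    from .clustering import kmeans_partition, select_k

    if cutoff is not None:
        rs = filter_until(rs, cutoff)
    rs = first_records(rs)
    if len(rs) == 0:
        raise ValueError("no records remain after filtering")
    pts = rs.coordinates()
    profile = None
    if k is None:
        k, profile = select_k(pts, k_min=k_range[0], k_max=k_range[1], seed=seed, n_restarts=n_restarts)
    part = kmeans_partition(pts, k, seed=seed, n_restarts=n_restarts)
    out = []
    for c in range(k):
        cpts = pts[part.labels == c]
        gp = rossmo_surface(cpts, gp_params, cluster_id=c)
        out.append(ClusterGeoprofile(cluster_id=c, points=cpts, geoprofile=gp, origin=estimate_origin(gp, q)))
    return part, profile, out
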