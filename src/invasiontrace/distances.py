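"""Great-circle and planar distance helpers on (lon, lat) arrays."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

__all__ = ["haversine_km", "pairwise_distances", "destination_point", "EARTH_RADIUS_KM"]


def haversine_km(a, b) -> np.ndarray:
    """Great-circle distance in km between broadcastable (..., 2) lon/lat arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances(x, y, metric: str) -> np.ndarray:
    """(n, m) distance matrix between (n, 2) and (m, 2) lon/lat points.

    metric: "euclidean_degrees" (planar, in degrees) or "haversine_km".
    """
    x = np.asarray(x, dtype=float).reshape(-1, 2)
    y = np.asarray(y, dtype=float).reshape(-1, 2)
    if metric == "euclidean_degrees":
        from scipy.spatial.distance import cdist

        return cdist(x, y)
    if metric == "haversine_km":
        return haversine_km(x[:, None, :], y[None, :, :])
    raise ValueError(f"unknown metric {metric!r}")


def destination_point(lon, lat, bearing_rad, distance_km):
    """Destination (lon, lat) after moving `distance_km` along `bearing_rad`.

    Standard great-circle destination formula; inputs broadcast elementwise.
    """
    lon1 = np.radians(np.asarray(lon, dtype=float))
    lat1 = np.radians(np.asarray(lat, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.asarray(bearing_rad, dtype=float)
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    lon_out = np.degrees(lon2)
    lon_out = (lon_out + 180.0) % 360.0 - 180.0
    return lon_out, np.degrees(lat2)
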