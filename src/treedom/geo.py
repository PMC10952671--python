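"""Planar projection and great-circle distances for plot coordinates.

Inventory plots carry WGS84 latitude/longitude. Two derived geometries are
needed: an equal-area planar frame (for square grid cells, so that cells
cover equal ground area regardless of latitude) and great-circle pairwise
distances in km (for distance-decay curves).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import haversine_distances

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088


def equal_area_xy(
    lat: np.ndarray, lon: np.ndarray, lat0: float | None = None, lon0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project lat/lon (degrees) to a Lambert cylindrical equal-area plane, km.

    The projection is centred on (`lat0`, `lon0`), by default the centroid of
    the input points, so distortion is small over a regional study window.

    x = R * (lon - lon0) * cos(lat0),  y = R * sin(lat) / cos(lat0)
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates outside WGS84 bounds")
    if lat0 is None:
        lat0 = float(np.mean(lat))
    if lon0 is None:
        lon0 = float(np.mean(lon))
    c = np.cos(np.radians(lat0))
    x = EARTH_RADIUS_KM * np.radians(lon - lon0) * c
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat)) / c
    return x, y


def inverse_equal_area(
    x: np.ndarray, y: np.ndarray, lat0: float, lon0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`equal_area_xy` (used by the synthetic landscape)."""
    c = np.cos(np.radians(lat0))
    lon = lon0 + np.degrees(np.asarray(x, dtype=float) / (EARTH_RADIUS_KM * c))
    s = np.clip(np.asarray(y, dtype=float) * c / EARTH_RADIUS_KM, -1.0, 1.0)
    lat = np.degrees(np.arcsin(s))
    return lat, lon


def pairwise_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle (haversine) distances in km."""
    pts = np.radians(np.column_stack([np.asarray(lat, float), np.asarray(lon, float)]))
    d = haversine_distances(pts) * EARTH_RADIUS_KM
    np.fill_diagonal(d, 0.0)
    return d
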