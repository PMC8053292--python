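"""Great-circle and planar distance helpers on geographic coordinates.

Coordinates are (latitude, longitude) in decimal degrees throughout the
package. Distances are kilometres. The geodesic metric is the haversine
formula on a sphere of radius :data:`EARTH_RADIUS_KM`; the planar metric is
an equirectangular approximation useful for synthetic grids where exact
sphericity is irrelevant.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: km per degree of latitude on the reference sphere
KM_PER_DEG_LAT = EARTH_RADIUS_KM * np.pi / 180.0


def _validate(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def haversine_km(a, b) -> np.ndarray | float:
    """Great-circle distance in km between coordinate pairs ``a`` and ``b``.

    Parameters
    ----------
    a, b : tuple of (lat, lon)
        Scalars or broadcastable arrays, decimal degrees.

    Returns
    -------
    float or ndarray
        Nonnegative distance; zero iff the points coincide.
    """
    lat1, lon1 = (np.asarray(x, dtype=float) for x in a)
    lat2, lon2 = (np.asarray(x, dtype=float) for x in b)
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def planar_km(a, b) -> np.ndarray | float:
    """Equirectangular distance in km (local flat-earth approximation)."""
    lat1, lon1 = (np.asarray(x, dtype=float) for x in a)
    lat2, lon2 = (np.asarray(x, dtype=float) for x in b)
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    latm = np.radians((lat1 + lat2) / 2.0)
    dy = (lat2 - lat1) * KM_PER_DEG_LAT
    dx = (lon2 - lon1) * KM_PER_DEG_LAT * np.cos(latm)
    d = np.hypot(dx, dy)
    if d.ndim == 0:
        return float(d)
    return d


def cross_distance_km(
    points_a: np.ndarray, points_b: np.ndarray, metric: str = "geodesic"
) -> np.ndarray:
    """All-pairs distance matrix (n, m) between two (k, 2) lat/lon arrays."""
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    a = (pa[:, 0][:, None], pa[:, 1][:, None])
    b = (pb[:, 0][None, :], pb[:, 1][None, :])
    if metric == "geodesic":
        return np.atleast_2d(haversine_km(a, b))
    if metric == "planar":
        return np.atleast_2d(planar_km(a, b))
    raise ValueError(f"unknown metric {metric!r}")


def offset_north_km(lat: float, lon: float, d_km: float) -> tuple[float, float]:
    """Point exactly ``d_km`` due north of (lat, lon) along the meridian.

    Along a meridian the haversine distance is exactly R * dphi, so this
    yields points at a known great-circle distance — handy for fixtures.
    """
    return lat + d_km / KM_PER_DEG_LAT, lon


def jitter_coords(
    lat: np.ndarray, lon: np.ndarray, sd_km: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian displacement with standard deviation sd_km."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dy = rng.normal(0.0, sd_km, size=lat.shape)
    dx = rng.normal(0.0, sd_km, size=lon.shape)
    new_lat = lat + dy / KM_PER_DEG_LAT
    new_lon = lon + dx / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return new_lat, new_lon
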