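"""Spherical geodesy and circular-angle arithmetic.

All geodesic computations use a sphere of radius 6371.0088 km (the IUGG mean
Earth radius).  Angles are handled in radians internally; degrees appear only
at the API boundary.  Bearings are degrees clockwise from geographic north in
[0, 360); longitudes are normalized to [-180, 180).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "normalize_lon",
    "normalize_bearing",
    "angular_difference",
    "signed_rotation",
    "great_circle_distance",
    "initial_bearing",
    "geographic_midpoint",
    "destination_point",
]


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into the half-open interval [-180, 180)."""
    return (lon + 180.0) % 360.0 - 180.0


def normalize_bearing(bearing):
    """Wrap a compass bearing (degrees) into [0, 360). Array-safe."""
    return np.asarray(bearing) % 360.0 if np.ndim(bearing) else bearing % 360.0


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere; lat in [-90, 90], lon normalized to [-180, 180)."""

    lat: float
    lon: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", normalize_lon(self.lon))


def angular_difference(a, b):
    """Unsigned angle between two bearings, in radians in [0, pi].

    Symmetric and wraparound-aware: (350 deg, 10 deg) -> 20 deg.  Accepts
    scalars or arrays of bearings in degrees.
    """
    d = (np.asarray(b, dtype=float) - np.asarray(a, dtype=float)) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    out = np.deg2rad(d)
    return float(out) if out.ndim == 0 else out


def signed_rotation(base, other):
    """Sign of the rotation from ``base`` to ``other`` (bearings in degrees).

    The difference is wrapped to (-180, 180]; returns +1 when ``other`` lies
    clockwise of ``base``, -1 when counter-clockwise, and 0 when the bearings
    coincide or are antipodal (rotation direction undefined).  Array-safe.
    """
    d = (np.asarray(other, dtype=float) - np.asarray(base, dtype=float)) % 360.0
    out = np.where((d == 0.0) | (d == 180.0), 0, np.where(d < 180.0, 1, -1))
    return int(out) if out.ndim == 0 else out


def great_circle_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points in kilometers (haversine)."""
    return float(
        great_circle_distance_deg(a.lat, a.lon, b.lat, b.lon)
    )


def great_circle_distance_deg(lat1, lon1, lat2, lon2):
    """Vectorized haversine distance (km) on coordinate arrays in degrees."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Initial great-circle bearing at ``a`` toward ``b``, degrees in [0, 360).

    Raises ValueError for coincident points, where the bearing is undefined.
    """
    out = initial_bearing_deg(a.lat, a.lon, b.lat, b.lon)
    if a.lat == b.lat and a.lon == b.lon:
        raise ValueError("bearing undefined for coincident points")
    return float(out)


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Vectorized initial bearing (degrees in [0, 360)) on degree arrays."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dl = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    x = np.sin(dl) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.rad2deg(np.arctan2(x, y)) % 360.0


def geographic_midpoint(a: GeoPoint, b: GeoPoint) -> GeoPoint:
    """Midpoint of the great-circle arc between two points.

    Raises ValueError for antipodal points (the midpoint is ambiguous).
    """
    va, vb = _unit_vector(a), _unit_vector(b)
    m = va + vb
    n = np.linalg.norm(m)
    if n < 1e-12:
        raise ValueError("midpoint ambiguous for antipodal points")
    m /= n
    lat = math.degrees(math.asin(np.clip(m[2], -1.0, 1.0)))
    lon = math.degrees(math.atan2(m[1], m[0]))
    return GeoPoint(lat, normalize_lon(lon))


def destination_point(p: GeoPoint, bearing: float, distance_km: float) -> GeoPoint:
    """Point reached from ``p`` along the initial ``bearing`` after ``distance_km``."""
    d = distance_km / EARTH_RADIUS_KM
    th = math.radians(bearing)
    p1 = math.radians(p.lat)
    l1 = math.radians(p.lon)
    p2 = math.asin(
        math.sin(p1) * math.cos(d) + math.cos(p1) * math.sin(d) * math.cos(th)
    )
    l2 = l1 + math.atan2(
        math.sin(th) * math.sin(d) * math.cos(p1),
        math.cos(d) - math.sin(p1) * math.sin(p2),
    )
    return GeoPoint(math.degrees(p2), normalize_lon(math.degrees(l2)))


def great_circle_path(a: GeoPoint, b: GeoPoint, n: int = 256) -> np.ndarray:
    """``n`` points (lat, lon) along the great circle from ``a`` to ``b``,
    endpoints included, by spherical linear interpolation."""
    va, vb = _unit_vector(a), _unit_vector(b)
    omega = math.acos(float(np.clip(np.dot(va, vb), -1.0, 1.0)))
    if omega < 1e-12:
        return np.repeat([[a.lat, a.lon]], n, axis=0)
    ts = np.linspace(0.0, 1.0, n)
    pts = (
        np.sin((1 - ts)[:, None] * omega) * va[None, :]
        + np.sin(ts[:, None] * omega) * vb[None, :]
    ) / math.sin(omega)
    lat = np.rad2deg(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(pts[:, 1], pts[:, 0]))
    return np.column_stack([lat, (lon + 180.0) % 360.0 - 180.0])


def _unit_vector(p: GeoPoint) -> np.ndarray:
    lat, lon = math.radians(p.lat), math.radians(p.lon)
    return np.array(
        [math.cos(lat) * math.cos(lon), math.cos(lat) * math.sin(lon), math.sin(lat)]
    )
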