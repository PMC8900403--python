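"""Stopover-corridor estimation and the range of preferred directions.

Migrants heading for a broad stopover region do not aim at a single point:
from any position en route there is a *range* of acceptable bearings, bounded
by the bearings to the western- and easternmost edges of the corridor.  The
range narrows with distance (a distant region subtends a small angle) and
widens on approach.

The corridor itself is estimated from the tracks as the candidate latitude
where crossing longitudes are least dispersed (the population "pinch point"),
with boundaries at the extreme crossing longitudes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import (
    GeoPoint,
    angular_difference,
    geographic_midpoint,
    initial_bearing,
    normalize_bearing,
    signed_rotation,
)

KM_PER_DEG_LAT = 111.19492664455873  # pi * R / 180

__all__ = ["Corridor", "PreferredRange", "estimate_corridor", "preferred_range"]


@dataclass(frozen=True)
class Corridor:
    """West/east boundary points of the narrowest corridor crossing."""

    west: GeoPoint
    east: GeoPoint
    band_lat: float
    metric: str = "sd"

    def __post_init__(self):
        if self.west.lon > self.east.lon:
            raise ValueError("corridor west boundary must lie west of east")

    @property
    def midpoint(self) -> GeoPoint:
        return geographic_midpoint(self.west, self.east)

    # -- persistence --------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "west": {"lat": self.west.lat, "lon": self.west.lon},
            "east": {"lat": self.east.lat, "lon": self.east.lon},
            "midpoint": {"lat": self.midpoint.lat, "lon": self.midpoint.lon},
            "band_lat": self.band_lat,
            "metric": self.metric,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "Corridor":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            west=GeoPoint(**doc["west"]),
            east=GeoPoint(**doc["east"]),
            band_lat=doc["band_lat"],
            metric=doc.get("metric", "sd"),
        )


@dataclass(frozen=True)
class PreferredRange:
    """Bearings from a focal point to the corridor edges and their midpoint.

    ``d_west``/``d_east`` are the bearings to the corridor boundary points,
    ``d_mid`` the angular midpoint of the minor arc between them, and
    ``half_width_rad`` the angle from the midpoint to either edge.
    """

    d_west: float
    d_east: float
    d_mid: float
    half_width_rad: float

    def __post_init__(self):
        if not 0.0 <= self.half_width_rad < math.pi / 2:
            raise ValueError("preferred-range half-width must be in [0, pi/2)")


_METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "sd": lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
    "iqr": lambda x: float(np.subtract(*np.percentile(x, [75, 25]))),
    "range": lambda x: float(np.ptp(x)),
}


def _crossing_lons(track: pd.DataFrame, lat0: float) -> list[float]:
    """Longitudes where a track (fix table) crosses latitude ``lat0``,
    linearly interpolated between the straddling fixes."""
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    out = []
    for i in range(len(lat) - 1):
        a, b = lat[i], lat[i + 1]
        if a == lat0:
            out.append(lon[i])
        elif (a < lat0 < b) or (b < lat0 < a):
            f = (lat0 - a) / (b - a)
            out.append(lon[i] + f * (lon[i + 1] - lon[i]))
    return out


def estimate_corridor(
    tracks: Iterable[pd.DataFrame],
    candidate_lats: Sequence[float],
    metric: str = "sd",
    boundary_quantiles: tuple[float, float] | None = None,
) -> Corridor:
    """Find the candidate latitude with the least crossing-longitude spread.

    Dispersion is measured in great-circle kilometers at the crossing
    latitude using the chosen metric (sd, iqr or range); ties go to the
    southernmost candidate.  Boundaries default to the extreme crossing
    longitudes; ``boundary_quantiles=(lo, hi)`` substitutes quantiles for
    robustness studies.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown dispersion metric {metric!r}")
    tracks = list(tracks)
    best = None
    for lat0 in sorted(candidate_lats):
        lons = []
        for k, tr in enumerate(tracks):
            cross = _crossing_lons(tr, lat0)
            if not cross:
                warnings.warn(f"track {k} does not cross latitude {lat0}; skipped")
                continue
            lons.append(cross[0])  # first crossing
        if len(lons) < 2:
            continue
        arr = np.asarray(lons)
        disp_km = _METRICS[metric](arr) * KM_PER_DEG_LAT * math.cos(math.radians(lat0))
        if best is None or disp_km < best[0]:
            best = (disp_km, lat0, arr)
    if best is None:
        raise ValueError("fewer than 2 tracks cross every candidate latitude")
    _, band_lat, lons = best
    if boundary_quantiles is not None:
        lo, hi = np.percentile(lons, [100 * q for q in boundary_quantiles])
    else:
        lo, hi = float(np.min(lons)), float(np.max(lons))
    return Corridor(
        west=GeoPoint(band_lat, lo),
        east=GeoPoint(band_lat, hi),
        band_lat=band_lat,
        metric=metric,
    )


def preferred_range(p: GeoPoint, corridor: Corridor) -> PreferredRange:
    """Range of preferred directions from ``p`` toward the corridor.

    ``p`` must lie strictly south of the corridor band.  The midpoint
    direction is the angular midpoint of the minor arc from the west-boundary
    bearing to the east-boundary bearing (not, in general, the bearing to the
    geographic midpoint).
    """
    if p.lat >= corridor.band_lat:
        raise ValueError("focal point must lie strictly south of the corridor band")
    if (p.lat, p.lon) == (corridor.west.lat, corridor.west.lon):
        raise ValueError("focal point coincides with a corridor boundary")
    d_w = initial_bearing(p, corridor.west)
    if (corridor.west.lat, corridor.west.lon) == (corridor.east.lat, corridor.east.lon):
        return PreferredRange(d_w, d_w, d_w, 0.0)
    d_e = initial_bearing(p, corridor.east)
    sep = angular_difference(d_w, d_e)  # minor arc, radians in [0, pi]
    if sep >= math.pi - 1e-12:
        raise ValueError("corridor subtends a degenerate (antipodal) arc")
    s = signed_rotation(d_w, d_e)  # rotation sense from west edge to east edge
    d_mid = normalize_bearing(d_w + (s or 1) * math.degrees(sep) / 2.0)
    return PreferredRange(d_w, d_e, float(d_mid), sep / 2.0)
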