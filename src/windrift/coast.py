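"""Coastline handling: land/sea attribution and track-coast intersection.

A coastline is supplied as GeoJSON containing land polygons (Polygon /
MultiPolygon features; LineString features are accepted as bare coast lines
for intersection-only use).  Attribution and intersection are done in
geographic coordinates with shapely; distances to the coast are converted to
kilometers with the local metric (1 deg lat = 111.195 km, longitudes scaled
by cos(lat)), which is adequate at coastal scales.
"""

from __future__ import annotations

import json
import math

import numpy as np
from shapely.geometry import LineString, Point, shape
from shapely.ops import unary_union
from shapely.prepared import prep

from .geo import EARTH_RADIUS_KM

KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0  # 111.195 km


class Coastline:
    """Land polygons plus their boundary polyline."""

    def __init__(self, land_polygons=(), coast_lines=()):
        self.land = unary_union(list(land_polygons)) if land_polygons else None
        lines = list(coast_lines)
        if self.land is not None:
            lines.append(self.land.boundary)
        if not lines:
            raise ValueError("coastline requires at least one polygon or line")
        self.boundary = unary_union(lines)
        self._prepared = prep(self.land) if self.land is not None else None

    @classmethod
    def from_geojson(cls, path) -> "Coastline":
        with open(path) as fh:
            doc = json.load(fh)
        geoms = []
        if doc.get("type") == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in doc["features"]]
        elif doc.get("type") == "Feature":
            geoms = [shape(doc["geometry"])]
        else:
            geoms = [shape(doc)]
        polys = [g for g in geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        lines = [g for g in geoms if g.geom_type in ("LineString", "MultiLineString")]
        return cls(polys, lines)

    def onshore(self, lats, lons, coastal_buffer_km: float = 1.0) -> np.ndarray:
        """Boolean onshore mask; points within ``coastal_buffer_km`` of the
        coast count as onshore (telemetry error exceeds coastline precision)."""
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        out = np.zeros(lats.shape, dtype=bool)
        for i, (la, lo) in enumerate(zip(lats, lons)):
            p = Point(lo, la)
            if self._prepared is not None and self._prepared.contains(p):
                out[i] = True
            elif self.distance_km(la, lo) <= coastal_buffer_km:
                out[i] = True
        return out

    def distance_km(self, lat: float, lon: float) -> float:
        """Approximate distance from a point to the coast polyline in km."""
        d_deg = self.boundary.distance(Point(lon, lat))
        # local anisotropy: scale by the worse (smaller) km-per-degree axis is
        # unnecessary at buffer scales; use the latitude-circle average
        scale = KM_PER_DEG * (1.0 + math.cos(math.radians(lat))) / 2.0
        return d_deg * scale

    def first_crossing(self, lats, lons):
        """First intersection of the polyline through (lats, lons) with the
        coast, walking the track in order.  Returns (lat, lon) or None."""
        pts = list(zip(np.asarray(lons, float), np.asarray(lats, float)))
        for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
            seg = LineString([(x1, y1), (x2, y2)])
            hit = seg.intersection(self.boundary)
            if hit.is_empty:
                continue
            cands = _points_of(hit)
            # earliest hit along the segment
            cands.sort(key=lambda q: seg.project(q))
            q = cands[0]
            return float(q.y), float(q.x)
        return None


def _points_of(geom) -> list[Point]:
    if geom.geom_type == "Point":
        return [geom]
    if hasattr(geom, "geoms"):
        out = []
        for g in geom.geoms:
            out.extend(_points_of(g))
        return out
    # line overlap: take representative endpoints
    return [Point(c) for c in geom.coords]
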