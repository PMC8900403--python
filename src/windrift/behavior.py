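"""Circular classification of in-flight responses to wind.

Each track segment is assigned exactly one of six behaviors by comparing
three direction-only vectors on the circle: the realized track direction
(r), the wind flow direction (w), and the range of preferred directions
[d_west, d_east] with angular midpoint d and half-width theta_dd.

Four unsigned angles drive the decision: theta_rw (track vs wind), theta_rd
(track vs range midpoint), theta_wd (wind vs range midpoint) and theta_dd
(the range half-width), with two tolerances: tau1 (combined imprecision of
track and wind directions, default 0.2 rad ~ 11.46 deg) and tau2 (track
imprecision alone, default 0.1 rad ~ 5.73 deg).

The hierarchical decision list:

1. track ~ wind (theta_rw <= tau1):
       inside the range (theta_rd <= theta_dd + tau2) -> ``supported``,
       otherwise -> ``full_drift``;
2. otherwise, inside the range -> ``full_compensation``;
3. otherwise compare rotation signs from the range midpoint to the track
   (s_r) and to the wind (s_w):
       opposite signs (midpoint lies between track and wind)
           -> ``overcompensation``;
       same side with theta_rd <= theta_wd (track between wind and midpoint)
           -> ``partial_compensation``;
       same side with theta_rd > theta_wd (wind between track and midpoint)
           -> ``overdrift``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corridor import Corridor, PreferredRange, preferred_range
from .geo import GeoPoint, angular_difference, signed_rotation

#: The closed set of behavior labels.
LABELS = (
    "supported",
    "full_drift",
    "full_compensation",
    "partial_compensation",
    "overcompensation",
    "overdrift",
)

__all__ = ["LABELS", "Tolerances", "ClassificationGeometry", "classify",
           "classify_angles", "classify_track"]


@dataclass(frozen=True)
class Tolerances:
    """Angular tolerances in radians; tau1 covers the combined imprecision of
    the track and wind directions, tau2 the track direction alone."""

    tau1: float = 0.2
    tau2: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.tau2 <= self.tau1 < math.pi / 2:
            raise ValueError("require 0 <= tau2 <= tau1 < pi/2")


@dataclass(frozen=True)
class ClassificationGeometry:
    """The angles and rotation signs extracted from one (r, w, range) triple."""

    theta_rw: float
    theta_rd: float
    theta_wd: float
    theta_dd: float
    s_r: int
    s_w: int


def classify_angles(theta_rw, theta_rd, theta_wd, theta_dd, s_r, s_w,
                    tol: Tolerances = Tolerances()) -> np.ndarray:
    """Vectorized decision list on precomputed geometry (angles in radians).

    Returns an integer array indexing into :data:`LABELS`.
    """
    theta_rw = np.asarray(theta_rw, dtype=float)
    theta_rd = np.asarray(theta_rd, dtype=float)
    theta_wd = np.asarray(theta_wd, dtype=float)
    theta_dd = np.asarray(theta_dd, dtype=float)
    s_r = np.asarray(s_r)
    s_w = np.asarray(s_w)

    in_range = theta_rd <= theta_dd + tol.tau2
    near_wind = theta_rw <= tol.tau1

    # rule 3 defaults, overwritten by rules 1-2 below
    opposite = s_r * s_w < 0
    out = np.where(
        opposite,
        LABELS.index("overcompensation"),
        np.where(
            theta_rd <= theta_wd,
            LABELS.index("partial_compensation"),
            LABELS.index("overdrift"),
        ),
    )
    out = np.where(near_wind & in_range, LABELS.index("supported"), out)
    out = np.where(near_wind & ~in_range, LABELS.index("full_drift"), out)
    out = np.where(~near_wind & in_range, LABELS.index("full_compensation"), out)
    return out


def geometry(track_dir: float, wind_dir: float, prange: PreferredRange) -> ClassificationGeometry:
    """Compute the classification geometry for one segment (degrees in)."""
    return ClassificationGeometry(
        theta_rw=angular_difference(track_dir, wind_dir),
        theta_rd=angular_difference(track_dir, prange.d_mid),
        theta_wd=angular_difference(wind_dir, prange.d_mid),
        theta_dd=prange.half_width_rad,
        s_r=signed_rotation(prange.d_mid, track_dir),
        s_w=signed_rotation(prange.d_mid, wind_dir),
    )


def classify(
    track_dir: float,
    wind_dir: float,
    prange: PreferredRange,
    tol: Tolerances = Tolerances(),
) -> str:
    """Assign one behavior label to a single segment (directions in degrees).

    Raises ValueError when either direction is undefined (NaN): calm-wind or
    zero-displacement segments must be excluded upstream.
    """
    if not np.isfinite(track_dir):
        raise ValueError("track direction undefined")
    if not np.isfinite(wind_dir):
        raise ValueError("wind direction undefined (calm wind)")
    g = geometry(track_dir, wind_dir, prange)
    idx = classify_angles(g.theta_rw, g.theta_rd, g.theta_wd, g.theta_dd,
                          g.s_r, g.s_w, tol)
    return LABELS[int(idx)]


def classify_track(
    segments: pd.DataFrame,
    corridor: Corridor,
    tol: Tolerances = Tolerances(),
    track_col: str = "heading_deg",
    wind_col: str = "wind_dir",
) -> pd.DataFrame:
    """Label every annotated segment of a track table.

    ``segments`` must carry the realized direction (``track_col``) and the
    selected-altitude wind direction (``wind_col``); the preferred range is
    recomputed at every segment start.  Segments with undefined heading or
    wind are labeled NaN and counted in the ``skipped`` attribute of the
    result (``result.attrs["n_skipped"]``).
    """
    out = segments.copy()
    labels = []
    t_rw, t_rd, t_wd, t_dd = [], [], [], []
    skipped = 0
    for row in out.itertuples(index=False):
        r = getattr(row, track_col)
        w = getattr(row, wind_col)
        start = GeoPoint(row.lat1, row.lon1)
        if not (np.isfinite(r) and np.isfinite(w)) or start.lat >= corridor.band_lat:
            skipped += 1
            labels.append(None)
            t_rw.append(np.nan), t_rd.append(np.nan)
            t_wd.append(np.nan), t_dd.append(np.nan)
            continue
        pr = preferred_range(start, corridor)
        g = geometry(r, w, pr)
        labels.append(classify(r, w, pr, tol))
        t_rw.append(g.theta_rw), t_rd.append(g.theta_rd)
        t_wd.append(g.theta_wd), t_dd.append(g.theta_dd)
    out["theta_rw"] = t_rw
    out["theta_rd"] = t_rd
    out["theta_wd"] = t_wd
    out["theta_dd"] = t_dd
    out["behavior"] = labels
    out.attrs["n_skipped"] = skipped
    return out
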