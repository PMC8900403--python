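"""Gridded wind access, tailwind/crosswind decomposition, altitude selection.

Winds live on a regular (time, level, lat, lon) grid — an ERA5-style
reanalysis slab — with eastward (u) and northward (v) components in m/s at
the seven pressure levels birds commonly use: 1000, 925, 850, 775, 700, 600
and 500 hPa.  The wind *flow direction* is the compass direction the wind
blows toward, atan2(u, v) as a bearing.

Wind support along a travel direction theta is the signed projection

    ws = cos(atan2(u, v) - theta) * sqrt(u^2 + v^2)

(positive = tailwind); crosswind is the perpendicular component, positive to
the right of theta.  The decomposition conserves energy:
ws^2 + cw^2 = u^2 + v^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

from .geo import GeoPoint

#: The seven pressure levels (hPa) and their nominal altitudes (m a.s.l.).
PRESSURE_LEVELS = (1000, 925, 850, 775, 700, 600, 500)
LEVEL_ALTITUDE_M = {
    1000: 100,
    925: 750,
    850: 1500,
    775: 2250,
    700: 3000,
    600: 3400,
    500: 5500,
}
#: Levels at or below 3000 m a.s.l. — the "lower five".
LOWER_FIVE = (1000, 925, 850, 775, 700)

__all__ = [
    "PRESSURE_LEVELS",
    "LEVEL_ALTITUDE_M",
    "LOWER_FIVE",
    "WindGrid",
    "WindVector",
    "AltitudePolicy",
    "wind_speed_dir",
    "wind_support",
    "crosswind",
    "interpolate_wind",
    "select_altitude",
]


@dataclass(frozen=True)
class WindVector:
    """One wind observation: components, magnitude and flow direction."""

    u: float
    v: float

    @property
    def speed(self) -> float:
        return float(np.hypot(self.u, self.v))

    @property
    def flow_dir(self) -> float:
        """Compass direction the wind blows toward, degrees in [0, 360)."""
        if self.speed == 0.0:
            raise ValueError("flow direction undefined for calm wind")
        return float(np.rad2deg(np.arctan2(self.u, self.v)) % 360.0)


def wind_speed_dir(u, v):
    """(speed m/s, flow direction deg) from components; direction is NaN
    where the wind is calm.  Array-safe."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    with np.errstate(invalid="ignore"):
        direction = np.where(speed > 0, np.rad2deg(np.arctan2(u, v)) % 360.0, np.nan)
    if speed.ndim == 0:
        return float(speed), float(direction)
    return speed, direction


def wind_support(u, v, theta_deg, magnitude: Literal["standard", "as_printed"] = "standard"):
    """Signed tailwind component along the bearing ``theta_deg`` (m/s).

    ``magnitude="as_printed"`` scales the projection by sqrt(u^2 * v^2)
    instead of the vector magnitude; it exists only for auditing against a
    published variant of the formula and breaks the conservation property.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    proj = np.cos(np.arctan2(u, v) - th)
    if magnitude == "standard":
        mag = np.hypot(u, v)
    elif magnitude == "as_printed":
        mag = np.sqrt(np.abs(u * u * v * v))
    else:
        raise ValueError(f"unknown magnitude convention {magnitude!r}")
    out = proj * mag
    return float(out) if out.ndim == 0 else out


def crosswind(u, v, theta_deg):
    """Signed lateral wind component, positive to the right of ``theta_deg``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    out = np.sin(np.arctan2(u, v) - th) * np.hypot(u, v)
    return float(out) if out.ndim == 0 else out


class WindGrid:
    """Regular hourly wind grid wrapping an xarray Dataset.

    Dimensions (time, level, lat, lon); variables ``u`` and ``v`` in m/s.
    """

    def __init__(self, ds: xr.Dataset):
        for var in ("u", "v"):
            if var not in ds:
                raise ValueError(f"wind dataset missing variable {var!r}")
        for dim in ("time", "level", "lat", "lon"):
            if dim not in ds.dims:
                raise ValueError(f"wind dataset missing dimension {dim!r}")
        for axis in ("lat", "lon"):
            vals = ds[axis].values
            if not (np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)):
                raise ValueError(f"{axis} axis must be strictly monotone")
        self.ds = ds.sortby(["lat", "lon"])

    @property
    def levels(self) -> tuple:
        return tuple(int(v) for v in self.ds["level"].values)

    # -- I/O ---------------------------------------------------------------
    def to_netcdf(self, path) -> None:
        enc = {
            "time": {"dtype": "float64", "units": "hours since 1970-01-01"},
            "level": {"dtype": "int32"},
        }
        self.ds.to_netcdf(path, engine="scipy", encoding=enc)

    @classmethod
    def from_netcdf(cls, path) -> "WindGrid":
        return cls(xr.load_dataset(path, engine="scipy"))

    @classmethod
    def from_csv(cls, path) -> "WindGrid":
        """Long-format fallback: columns time, level, lat, lon, u, v."""
        df = pd.read_csv(path, parse_dates=["time"])
        ds = df.set_index(["time", "level", "lat", "lon"]).to_xarray()
        return cls(ds)

    def to_csv(self, path) -> None:
        self.ds.to_dataframe().reset_index().to_csv(path, index=False)


def _nearest_hour_index(times: np.ndarray, t: np.datetime64) -> int:
    """Index of the grid hour nearest to t; exact half-hour ties go earlier."""
    t = np.datetime64(pd.Timestamp(t))
    diffs = (times - t) / np.timedelta64(1, "s")
    if t < times[0] or t > times[-1]:
        raise ValueError(f"time {t} outside wind grid time axis")
    abs_d = np.abs(diffs)
    best = np.min(abs_d)
    cands = np.where(abs_d == best)[0]
    return int(cands[0])  # ties resolve to the earlier hour


def interpolate_wind(
    grid: WindGrid, point: GeoPoint, time, level: int
) -> WindVector:
    """Bilinear (lat, lon) interpolation of u and v at the nearest grid hour.

    Raises ValueError naming the offending axis for out-of-bounds queries.
    """
    ds = grid.ds
    lats = ds["lat"].values
    lons = ds["lon"].values
    if not lats[0] <= point.lat <= lats[-1]:
        raise ValueError(f"lat {point.lat} outside wind grid lat axis")
    if not lons[0] <= point.lon <= lons[-1]:
        raise ValueError(f"lon {point.lon} outside wind grid lon axis")
    if level not in grid.levels:
        raise ValueError(f"level {level} not in wind grid level axis")
    it = _nearest_hour_index(ds["time"].values, time)
    slab = ds.isel(time=it).sel(level=level)
    u = float(slab["u"].interp(lat=point.lat, lon=point.lon, method="linear"))
    v = float(slab["v"].interp(lat=point.lat, lon=point.lon, method="linear"))
    return WindVector(u, v)


def wind_profile(grid: WindGrid, point: GeoPoint, time) -> dict[int, WindVector]:
    """The full 7-level wind profile at a place and time."""
    return {
        lev: interpolate_wind(grid, point, time, lev) for lev in grid.levels
    }


@dataclass(frozen=True)
class AltitudePolicy:
    """How a flight altitude (pressure level) is chosen per location.

    ``kind="fixed"`` pins one level; ``kind="max_lower5"`` / ``"max_all7"``
    pick the level maximizing wind support toward a direction, which is
    either the preferred direction ("preferred") or the realized track
    direction ("track").
    """

    kind: Literal["fixed", "max_lower5", "max_all7"]
    level: int | None = None
    direction: Literal["preferred", "track"] = "preferred"

    def __post_init__(self):
        if self.kind == "fixed":
            if self.level not in PRESSURE_LEVELS:
                raise ValueError(f"fixed policy needs a valid level, got {self.level}")
        elif self.kind not in ("max_lower5", "max_all7"):
            raise ValueError(f"unknown policy kind {self.kind!r}")

    @property
    def candidate_levels(self) -> tuple:
        if self.kind == "fixed":
            return (self.level,)
        return LOWER_FIVE if self.kind == "max_lower5" else PRESSURE_LEVELS

    @property
    def n_selectable(self) -> int:
        """Model-complexity proxy: how many levels the policy may choose from."""
        return len(self.candidate_levels)

    def label(self) -> str:
        if self.kind == "fixed":
            return f"fixed({self.level})"
        return f"{self.kind}({self.direction})"


#: The seven candidate policies compared in the ground-speed model selection.
SEVEN_POLICIES = (
    AltitudePolicy("fixed", 1000),
    AltitudePolicy("fixed", 925),
    AltitudePolicy("fixed", 850),
    AltitudePolicy("max_lower5", direction="preferred"),
    AltitudePolicy("max_lower5", direction="track"),
    AltitudePolicy("max_all7", direction="preferred"),
    AltitudePolicy("max_all7", direction="track"),
)


def annotate_segments(
    segments: pd.DataFrame,
    grid: WindGrid,
    corridor,
    policy: "AltitudePolicy",
    keep_profile: bool = True,
) -> pd.DataFrame:
    """Attach the selected-altitude wind to every track segment.

    For each segment the 7-level profile is interpolated at the segment's
    start fix and time; the policy picks the flight level (toward the
    preferred direction or the realized track direction), and the segment
    gains columns ``level``, ``u``, ``v``, ``wind_speed``, ``wind_dir``,
    ``ws`` and ``cw`` (support/crosswind relative to the preferred-range
    midpoint ``pref_dir``).  With ``keep_profile`` the raw per-level
    components ``u_<level>``/``v_<level>`` are retained for model selection.
    """
    from .corridor import preferred_range  # local import to avoid a cycle

    out = segments.copy()
    cols: dict[str, list] = {
        k: [] for k in ("pref_dir", "level", "u", "v", "wind_speed", "wind_dir", "ws", "cw")
    }
    prof_cols: dict[str, list] = {}
    if keep_profile:
        for lev in grid.levels:
            prof_cols[f"u_{lev}"] = []
            prof_cols[f"v_{lev}"] = []
    for row in out.itertuples(index=False):
        start = GeoPoint(row.lat1, row.lon1)
        profile = wind_profile(grid, start, row.t_start)
        if keep_profile:
            for lev, w in profile.items():
                prof_cols[f"u_{lev}"].append(w.u)
                prof_cols[f"v_{lev}"].append(w.v)
        if start.lat < corridor.band_lat:
            d_mid = preferred_range(start, corridor).d_mid
        else:
            d_mid = np.nan
        theta = d_mid if policy.direction == "preferred" else row.heading_deg
        if policy.kind != "fixed" and not np.isfinite(theta):
            for k in cols:
                cols[k].append(np.nan)
            continue
        lev, w = select_altitude(profile, theta, policy)
        speed, wdir = wind_speed_dir(w.u, w.v)
        cols["pref_dir"].append(d_mid)
        cols["level"].append(lev)
        cols["u"].append(w.u)
        cols["v"].append(w.v)
        cols["wind_speed"].append(speed)
        cols["wind_dir"].append(wdir)
        cols["ws"].append(wind_support(w.u, w.v, d_mid) if np.isfinite(d_mid) else np.nan)
        cols["cw"].append(crosswind(w.u, w.v, d_mid) if np.isfinite(d_mid) else np.nan)
    for k, vals in {**cols, **prof_cols}.items():
        out[k] = vals
    return out


def select_altitude(
    profile: dict[int, WindVector], theta_deg: float, policy: AltitudePolicy
) -> tuple[int, WindVector]:
    """Pick the pressure level per the policy; ties go to the lower altitude.

    ``profile`` must contain every candidate level of the policy.  ``theta``
    is the direction toward which support is maximized (preferred or track).
    """
    missing = [lev for lev in policy.candidate_levels if lev not in profile]
    if missing:
        raise ValueError(f"incomplete wind profile, missing levels {missing}")
    if policy.kind == "fixed":
        return policy.level, profile[policy.level]
    best_lev, best_ws = None, -np.inf
    # iterate from lowest altitude (highest pressure) so ties keep the lower
    for lev in sorted(policy.candidate_levels, reverse=True):
        w = profile[lev]
        ws = wind_support(w.u, w.v, theta_deg)
        if ws > best_ws:
            best_lev, best_ws = lev, ws
    return best_lev, profile[best_lev]
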