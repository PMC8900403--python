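"""Synthetic wind fields, behavioral agents, and a telemetry observation model.

The generator emulates the study conditions of a trans-hemispheric nonstop
flight: a ~8,000 km south-to-north corridor crossed by distinct wind regimes
(a rotating subtropical anticyclone near the departure latitudes, steady
trade winds, a calm convergence band), agents that respond to wind with a
known behavioral policy, and duty-cycled, error-class-labeled satellite
fixes.  Everything is deterministic given a seed.

Agent modes and the wind triangle (airspeed a, preferred bearing d, wind
crosswind component c relative to d):

* ``full_compensation`` — heading offset delta = arcsin(-c/a) cancels the
  crosswind so the realized track stays on d; infeasible when |c| > a, in
  which case the agent crabs at the maximum-effort +/-90 deg and the step is
  flagged.
* ``partial(f)`` — applies (1-f) of the full-compensation offset; f = 0 is
  full compensation, f = 1 is no correction (heading = d, classical drift in
  the slope sense: lateral ground velocity equals the crosswind).
* ``drift`` — downwind flight (heading = wind flow direction), so the
  realized direction equals the wind flow: the categorical full-drift
  behavior.  Falls back to heading = d in calm air.
* ``fixed_heading(theta)`` — constant heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

from .coast import Coastline
from .corridor import Corridor, preferred_range
from .geo import GeoPoint
from .wind import PRESSURE_LEVELS, WindGrid, crosswind, interpolate_wind

KM_PER_DEG_LAT = 111.19492664455873

__all__ = [
    "WindRegime",
    "WindScenario",
    "AgentPolicy",
    "GpsSampling",
    "ArgosSampling",
    "generate_wind_grid",
    "simulate_agent",
    "observe",
    "synthetic_coastline",
    "default_scenario",
]


# ---------------------------------------------------------------------------
# wind scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindRegime:
    """One latitudinal wind regime.

    kinds: ``uniform`` (constant u, v), ``anticyclone`` (solid-body rotation
    about a center, counter-clockwise as for a Southern-Hemisphere high;
    tangential speed = omega_ms_per_km * distance, capped), ``calm`` (zero
    mean flow, optional extra jitter).
    """

    kind: Literal["uniform", "anticyclone", "calm"]
    u: float = 0.0
    v: float = 0.0
    center_lat: float = 0.0
    center_lon: float = 0.0
    omega_ms_per_km: float = 0.01
    max_speed: float = 15.0
    sigma: float = 0.0

    def field_at(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "uniform":
            return np.full_like(lat, self.u), np.full_like(lat, self.v)
        if self.kind == "calm":
            return np.zeros_like(lat), np.zeros_like(lat)
        # anticyclone: flat-earth offsets from the center in km
        dy = (lat - self.center_lat) * KM_PER_DEG_LAT
        dx = (lon - self.center_lon) * KM_PER_DEG_LAT * np.cos(np.deg2rad(lat))
        r = np.hypot(dx, dy)
        speed = np.minimum(self.omega_ms_per_km * r, self.max_speed)
        with np.errstate(invalid="ignore", divide="ignore"):
            # counter-clockwise tangential unit vector (-dy, dx)/r
            u = np.where(r > 0, -speed * dy / r, 0.0)
            v = np.where(r > 0, speed * dx / r, 0.0)
        return u, v


@dataclass
class WindScenario:
    """Zoned wind field specification on a regular grid.

    ``zones`` is a list of (lat_min, lat_max, WindRegime) tiles; latitudes
    outside every zone are calm.  ``level_multipliers`` scales the base field
    per pressure level; node-wise Gaussian noise with sd ``noise_sd`` is
    added independently per level and hour.
    """

    zones: list
    lat_range: tuple[float, float] = (-46.0, 36.0)
    lon_range: tuple[float, float] = (-120.0, -60.0)
    resolution_deg: float = 0.5
    start_time: str = "2021-04-10T00:00"
    n_hours: int = 24
    noise_sd: float = 0.0
    level_multipliers: dict = field(default_factory=dict)
    seed: int = 0


def generate_wind_grid(scenario: WindScenario) -> WindGrid:
    """Materialize a scenario as an hourly (time, level, lat, lon) grid."""
    res = scenario.resolution_deg
    lats = np.arange(scenario.lat_range[0], scenario.lat_range[1] + res / 2, res)
    lons = np.arange(scenario.lon_range[0], scenario.lon_range[1] + res / 2, res)
    times = pd.date_range(scenario.start_time, periods=scenario.n_hours, freq="h")
    glon, glat = np.meshgrid(lons, lats)

    base_u = np.zeros_like(glat)
    base_v = np.zeros_like(glat)
    extra_sigma = np.zeros_like(glat)
    for lat_min, lat_max, regime in scenario.zones:
        m = (glat >= lat_min) & (glat < lat_max)
        u, v = regime.field_at(glat, glon)
        base_u[m] = u[m]
        base_v[m] = v[m]
        if regime.sigma > 0:
            extra_sigma[m] = regime.sigma

    rng = np.random.default_rng(scenario.seed)
    nt, nz = len(times), len(PRESSURE_LEVELS)
    u = np.empty((nt, nz, len(lats), len(lons)))
    v = np.empty_like(u)
    for iz, lev in enumerate(PRESSURE_LEVELS):
        mult = scenario.level_multipliers.get(lev, 1.0)
        u[:, iz] = base_u[None, :, :] * mult
        v[:, iz] = base_v[None, :, :] * mult
    sd = scenario.noise_sd
    if sd > 0 or (extra_sigma > 0).any():
        total_sd = np.sqrt(sd**2 + extra_sigma**2)
        u += rng.standard_normal(u.shape) * total_sd[None, None, :, :]
        v += rng.standard_normal(v.shape) * total_sd[None, None, :, :]
    ds = xr.Dataset(
        {
            "u": (("time", "level", "lat", "lon"), u),
            "v": (("time", "level", "lat", "lon"), v),
        },
        coords={
            "time": times,
            "level": list(PRESSURE_LEVELS),
            "lat": lats,
            "lon": lons,
        },
    )
    return WindGrid(ds)


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentPolicy:
    """Behavioral policy of a simulated migrant.

    ``airspeed`` defaults to 12.7 m/s, a plausible shorebird airspeed.
    ``level`` pins the flight pressure level so the ground truth is
    unambiguous (altitude selection is exercised separately).
    """

    mode: Literal["full_compensation", "partial", "drift", "fixed_heading"]
    airspeed: float = 12.7
    drift_fraction: float = 0.0  # f for mode="partial"
    fixed_heading_deg: float = 0.0
    #: below this wind speed a drift-mode agent reverts to the preferred
    #: course: there is no flow to follow in near-calm air
    drift_min_wind: float = 2.0
    step_h: float = 1.0
    level: int = 925

    def __post_init__(self):
        if self.airspeed <= 0:
            raise ValueError("airspeed must be positive")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValueError("drift fraction must be in [0, 1]")


SUBSTEP_H = 0.25  # flat-earth integration sub-step


def simulate_agent(
    policy: AgentPolicy,
    grid: WindGrid,
    start: GeoPoint,
    corridor: Corridor,
    seed: int = 0,
    start_time=None,
    max_steps: int = 400,
    stop_lat: float | None = None,
    hold_h: float = 0.0,
) -> pd.DataFrame:
    """Step an agent through the wind field until it reaches ``stop_lat``
    (default: the corridor band) or ``max_steps`` elapse.

    Returns the true track: one row per step with position and time at the
    step start, the wind sampled there, the commanded heading, the heading
    offset ``delta_deg`` from the preferred direction, the generating mode
    (ground truth) and an infeasibility flag for saturated compensation.
    With ``hold_h > 0`` the agent stays put for that long after stopping
    (the tag keeps reporting after arrival).
    """
    if start.lat >= corridor.band_lat:
        raise ValueError("agent must start south of the corridor band")
    stop_lat = corridor.band_lat if stop_lat is None else stop_lat
    t = pd.Timestamp(start_time) if start_time is not None else pd.Timestamp(
        grid.ds["time"].values[0]
    )
    lat, lon = start.lat, start.lon
    a = policy.airspeed
    rows = []
    for _ in range(max_steps):
        if lat >= stop_lat:
            break
        here = GeoPoint(lat, lon)
        try:
            w = interpolate_wind(grid, here, t, policy.level)
        except ValueError:
            break  # left the wind domain (or its time span): track ends here
        d = preferred_range(here, corridor).d_mid
        c = crosswind(w.u, w.v, d)
        infeasible = False
        if policy.mode == "fixed_heading":
            heading = policy.fixed_heading_deg
            delta = heading - d
        elif policy.mode == "drift":
            heading = w.flow_dir if w.speed >= policy.drift_min_wind else d
            delta = heading - d
        else:
            f = policy.drift_fraction if policy.mode == "partial" else 0.0
            if abs(c) <= a:
                delta_full = math.degrees(math.asin(-c / a))
            else:
                delta_full = -90.0 if c > 0 else 90.0
                infeasible = True
            delta = (1.0 - f) * delta_full
            heading = d + delta
        hr = math.radians(heading)
        gu = a * math.sin(hr) + w.u
        gv = a * math.cos(hr) + w.v
        rows.append(
            {
                "time": t,
                "lat": lat,
                "lon": lon,
                "true_mode": policy.mode,
                "heading_cmd_deg": heading % 360.0,
                "delta_deg": delta,
                "u": w.u,
                "v": w.v,
                "pref_dir": d,
                "infeasible": infeasible,
            }
        )
        # advance with flat-earth sub-steps (speeds in m/s -> degrees)
        n_sub = max(1, int(round(policy.step_h / SUBSTEP_H)))
        dt_s = policy.step_h * 3600.0 / n_sub
        for _s in range(n_sub):
            lat += gv * dt_s / 1000.0 / KM_PER_DEG_LAT
            lon += gu * dt_s / 1000.0 / (
                KM_PER_DEG_LAT * math.cos(math.radians(lat))
            )
        t = t + pd.Timedelta(hours=policy.step_h)
    # terminal position so the true track extends to where the agent stopped,
    # plus an optional stationary hold while the tag keeps reporting
    terminal_times = [t]
    if hold_h > 0:
        terminal_times.append(t + pd.Timedelta(hours=hold_h))
    for tt in terminal_times:
        rows.append(
            {
                "time": tt,
                "lat": lat,
                "lon": lon,
                "true_mode": policy.mode,
                "heading_cmd_deg": np.nan,
                "delta_deg": np.nan,
                "u": np.nan,
                "v": np.nan,
                "pref_dir": np.nan,
                "infeasible": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

#: Plausible isotropic position-error SDs (km) per quality class; these are
#: configuration defaults, not claims about any particular tag.
DEFAULT_CLASS_SD_KM = {"A3": 0.25, "A2": 0.5, "A1": 1.5, "A0": 5.0, "AA": 10.0, "AB": 20.0}
DEFAULT_CLASS_PROBS = {"A3": 0.18, "A2": 0.22, "A1": 0.25, "A0": 0.15, "AA": 0.12, "AB": 0.08}


@dataclass(frozen=True)
class GpsSampling:
    """GPS tag: a fix every ``every_h`` hours with ~10 m resolution."""

    every_h: float = 2.0
    noise_m: float = 10.0


@dataclass(frozen=True)
class ArgosSampling:
    """Duty-cycled Argos tag: ``on_h`` transmitting / ``off_h`` charging.

    Each transmission window yields two location-class fixes (an early and a
    late satellite pass), giving the ~3 h within-bout cadence typical of
    5-g solar tags; class labels are drawn from ``class_probs`` and position
    noise from the per-class SDs.
    """

    on_h: float = 5.0
    off_h: float = 24.0
    class_sd_km: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SD_KM))
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))


def _true_position(track: pd.DataFrame, when: pd.Timestamp):
    """Linear interpolation of the true track at an arbitrary time."""
    times = track["time"].to_numpy()
    tt = np.datetime64(when)
    if tt <= times[0]:
        return float(track["lat"].iloc[0]), float(track["lon"].iloc[0])
    if tt >= times[-1]:
        return float(track["lat"].iloc[-1]), float(track["lon"].iloc[-1])
    i = int(np.searchsorted(times, tt) - 1)
    f = (tt - times[i]) / (times[i + 1] - times[i])
    lat = track["lat"].iloc[i] + f * (track["lat"].iloc[i + 1] - track["lat"].iloc[i])
    lon = track["lon"].iloc[i] + f * (track["lon"].iloc[i + 1] - track["lon"].iloc[i])
    return float(lat), float(lon)


def observe(
    track: pd.DataFrame,
    sampling: GpsSampling | ArgosSampling,
    animal_id: str = "sim",
    seed: int = 0,
) -> pd.DataFrame:
    """Sample telemetry fixes from a true track.

    Returns the standard fix table (id, time, lat, lon, quality);
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(track["time"].iloc[0])
    t1 = pd.Timestamp(track["time"].iloc[-1])
    fix_times, qualities, sds = [], [], []
    if isinstance(sampling, GpsSampling):
        t = t0
        while t <= t1:
            fix_times.append(t)
            qualities.append("GPS")
            sds.append(sampling.noise_m / 1000.0)
            t += pd.Timedelta(hours=sampling.every_h)
    else:
        classes = list(sampling.class_probs)
        probs = np.array([sampling.class_probs[c] for c in classes], dtype=float)
        probs /= probs.sum()
        cycle = sampling.on_h + sampling.off_h
        w0 = t0
        while w0 <= t1:
            # two location-yielding passes per window: early and late
            offsets = (
                0.5 + 0.5 * rng.random(),
                sampling.on_h - 1.25 + 0.5 * rng.random(),
            )
            for off in offsets:
                ft = w0 + pd.Timedelta(hours=float(off))
                if ft > t1:
                    continue
                q = classes[int(rng.choice(len(classes), p=probs))]
                fix_times.append(ft)
                qualities.append(q)
                sds.append(sampling.class_sd_km[q])
            w0 += pd.Timedelta(hours=cycle)
    rows = []
    for ft, q, sd in zip(fix_times, qualities, sds):
        lat, lon = _true_position(track, ft)
        if sd > 0:
            lat += rng.standard_normal() * sd / KM_PER_DEG_LAT
            lon += rng.standard_normal() * sd / (
                KM_PER_DEG_LAT * math.cos(math.radians(lat))
            )
        rows.append({"id": animal_id, "time": ft, "lat": lat, "lon": lon, "quality": q})
    df = pd.DataFrame(rows, columns=["id", "time", "lat", "lon", "quality"])
    return df.sort_values("time", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# bundled demo scenario
# ---------------------------------------------------------------------------

def synthetic_coastline() -> tuple[Coastline, dict]:
    """Two synthetic land masses: a southern departure continent (coast at
    41 deg S) and a northern gulf coast (zonal coast at 30 deg N).  Returns
    the Coastline plus its GeoJSON document."""
    south = {
        "type": "Polygon",
        "coordinates": [[[-120, -60], [-50, -60], [-50, -41], [-120, -41], [-120, -60]]],
    }
    north = {
        "type": "Polygon",
        "coordinates": [[[-120, 30], [-50, 30], [-50, 60], [-120, 60], [-120, 30]]],
    }
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": "southern landmass"},
             "geometry": south},
            {"type": "Feature", "properties": {"name": "northern gulf coast"},
             "geometry": north},
        ],
    }
    from shapely.geometry import shape

    return Coastline([shape(south), shape(north)]), doc


def default_scenario(seed: int = 0, n_hours: int = 200,
                     resolution_deg: float = 2.0) -> WindScenario:
    """The bundled study-like wind field: an anticyclone off the departure
    coast, steady trades, a calm convergence band, weaker northern trades."""
    zones = [
        (-46.0, -20.0, WindRegime("anticyclone", center_lat=-33.0, center_lon=-90.0,
                                  omega_ms_per_km=0.012, max_speed=14.0)),
        (-20.0, 0.0, WindRegime("uniform", u=-4.0, v=6.0)),
        (0.0, 10.0, WindRegime("calm", sigma=1.5)),
        (10.0, 36.1, WindRegime("uniform", u=-3.0, v=4.0)),
    ]
    return WindScenario(
        zones=zones,
        resolution_deg=resolution_deg,
        n_hours=n_hours,
        noise_sd=0.8,
        seed=seed,
    )


def default_corridor() -> Corridor:
    """Stopover corridor used by the demo scenario (narrow band at 45 N)."""
    return Corridor(west=GeoPoint(45.0, -100.0), east=GeoPoint(45.0, -96.0),
                    band_lat=45.0)
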