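"""Track preparation: telemetry filtering, thinning, truncation, kinematics.

Fixes travel through this module as a pandas DataFrame with columns
``id`` (animal identifier), ``time`` (UTC datetime64), ``lat``, ``lon`` and
``quality`` (one of GPS, A3, A2, A1, A0, AA, AB — GPS best, Argos class B
worst).  All filters preserve row order, never add fixes, and are run to a
fixpoint so each is idempotent.

The cleaning cascade mirrors standard satellite-telemetry practice for
duty-cycled Argos/GPS tags on fast migrants:

1. a rate filter (implausible speeds, > 130 km/h) plus a redundancy filter
   (low-quality fixes sandwiched within 5 km of both temporal neighbors);
2. stopover removal (overland fixes that are both slow, < 3 m/s, and short,
   < 15 km to the next fix);
3. hourly thinning (keep the better-quality fix of any pair closer than 1 h,
   seeded random tie-break) and de-gapping (drop fixes preceding a > 12 h
   reporting gap);
4. truncation to the nonstop flight: from the first offshore fix showing
   directional departure through the first overland fix after the crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coast import Coastline
from .geo import (
    angular_difference,
    great_circle_distance_deg,
    initial_bearing_deg,
    signed_rotation,
)

#: Quality classes, best first: GPS, then Argos classes 3, 2, 1, 0, A, B.
QUALITY_ORDER = ("GPS", "A3", "A2", "A1", "A0", "AA", "AB")
QUALITY_RANK = {q: i for i, q in enumerate(QUALITY_ORDER)}
#: Argos classes the redundancy rule may remove (the low-quality tiers that
#: are passed through the hybrid filter rather than retained outright).
LOW_QUALITY = frozenset({"A0", "AA", "AB"})

FIX_COLUMNS = ["id", "time", "lat", "lon", "quality"]


def _check_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"fix table missing columns {missing}")
    bad = set(fixes["quality"]) - set(QUALITY_ORDER)
    if bad:
        raise ValueError(f"unknown quality classes {sorted(bad)}")
    return fixes.reset_index(drop=True)


def quality_rank(quality) -> np.ndarray:
    """Numeric quality rank, 0 = best (GPS) .. 6 = worst (Argos B)."""
    return np.asarray([QUALITY_RANK[q] for q in quality])


# ---------------------------------------------------------------------------
# rate / redundancy filter
# ---------------------------------------------------------------------------

def rate_redundancy_filter(
    fixes: pd.DataFrame,
    max_speed_kmh: float = 130.0,
    max_redundant_km: float = 5.0,
) -> pd.DataFrame:
    """Remove fixes implying implausible speeds or redundant low-quality fixes.

    The rate rule drops the *later* fix of any consecutive pair whose implied
    speed exceeds ``max_speed_kmh`` (greedy forward pass).  The redundancy
    rule drops low-quality fixes (Argos 0/A/B) lying within
    ``max_redundant_km`` of both temporal neighbors.  Both rules are applied
    alternately until the track is stable.
    """
    df = _check_fixes(fixes)
    if len(df) < 2:
        warnings.warn("fewer than 2 fixes; rate/redundancy filter is a no-op")
        return df
    while True:
        n0 = len(df)
        df = _rate_pass(df, max_speed_kmh)
        df = _redundancy_pass(df, max_redundant_km)
        if len(df) == n0:
            return df.reset_index(drop=True)


def _rate_pass(df: pd.DataFrame, max_speed_kmh: float) -> pd.DataFrame:
    if not np.isfinite(max_speed_kmh):
        return df
    keep = [0]
    for i in range(1, len(df)):
        j = keep[-1]
        dt_h = (df["time"].iloc[i] - df["time"].iloc[j]).total_seconds() / 3600.0
        if dt_h <= 0:
            raise ValueError("fixes must be strictly increasing in time")
        d_km = great_circle_distance_deg(
            df["lat"].iloc[j], df["lon"].iloc[j], df["lat"].iloc[i], df["lon"].iloc[i]
        )
        if d_km / dt_h <= max_speed_kmh:
            keep.append(i)
    return df.iloc[keep]


def _redundancy_pass(df: pd.DataFrame, max_redundant_km: float) -> pd.DataFrame:
    if max_redundant_km <= 0 or len(df) < 3:
        return df
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    d_prev = great_circle_distance_deg(lat[1:-1], lon[1:-1], lat[:-2], lon[:-2])
    d_next = great_circle_distance_deg(lat[1:-1], lon[1:-1], lat[2:], lon[2:])
    low = df["quality"].iloc[1:-1].isin(LOW_QUALITY).to_numpy()
    redundant = low & (d_prev <= max_redundant_km) & (d_next <= max_redundant_km)
    if not redundant.any():
        return df
    # drop only the first offender, then re-evaluate with fresh neighbors
    first = 1 + int(np.argmax(redundant))
    return df.drop(df.index[first])


# ---------------------------------------------------------------------------
# stopover removal
# ---------------------------------------------------------------------------

def remove_stopovers(
    fixes: pd.DataFrame,
    coastline: Coastline | None = None,
    onshore: np.ndarray | None = None,
    speed_min_ms: float = 3.0,
    dist_min_km: float = 15.0,
) -> pd.DataFrame:
    """Drop overland fixes that are both slow and nearly stationary.

    A fix is removed when it is onshore, its ground speed to the next fix is
    below ``speed_min_ms`` *and* the move to the next fix is shorter than
    ``dist_min_km``.  Offshore fixes are never touched.  Applied to a
    fixpoint, so whole stopover clusters collapse.
    """
    df = _check_fixes(fixes)
    if coastline is None and onshore is None:
        raise ValueError("remove_stopovers requires a coastline or onshore mask")
    if onshore is not None:
        df = df.assign(_onshore=np.asarray(onshore, dtype=bool))
    else:
        df = df.assign(_onshore=coastline.onshore(df["lat"], df["lon"]))
    while len(df) >= 2:
        lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
        dt_s = df["time"].diff().dt.total_seconds().to_numpy()[1:]
        d_km = great_circle_distance_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
        gs = d_km * 1000.0 / dt_s
        stopped = (
            df["_onshore"].to_numpy()[:-1]
            & (gs < speed_min_ms)
            & (d_km < dist_min_km)
        )
        if not stopped.any():
            break
        df = df.iloc[np.r_[~stopped, True]].reset_index(drop=True)
    return df.drop(columns="_onshore").reset_index(drop=True)


# ---------------------------------------------------------------------------
# thinning and de-gapping
# ---------------------------------------------------------------------------

def thin_and_degap(
    fixes: pd.DataFrame,
    max_rate_per_h: float = 1.0,
    max_gap_h: float = 12.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Thin to at most one fix per hour, then drop fixes before long gaps.

    Whenever two consecutive fixes are closer than ``1/max_rate_per_h`` hours,
    the lower-quality one is dropped; quality ties are broken at random with
    the supplied seed (bit-reproducible).  Afterwards any fix whose successor
    arrives more than ``max_gap_h`` hours later (strict) is removed.
    """
    df = _check_fixes(fixes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    window_h = 1.0 / max_rate_per_h
    while len(df) >= 2:
        dt_h = df["time"].diff().dt.total_seconds().to_numpy() / 3600.0
        close = np.where(dt_h[1:] < window_h)[0]
        if close.size == 0:
            break
        i = int(close[0])  # indices i, i+1 violate the rate
        ra = QUALITY_RANK[df["quality"].iloc[i]]
        rb = QUALITY_RANK[df["quality"].iloc[i + 1]]
        if ra < rb:
            drop = i + 1
        elif rb < ra:
            drop = i
        else:
            drop = i + int(rng.integers(2))
        df = df.drop(df.index[drop]).reset_index(drop=True)
    if len(df) >= 2:
        dt_next = (-df["time"].diff(-1).dt.total_seconds() / 3600.0).to_numpy()
        keep = ~(dt_next > max_gap_h)
        keep[-1] = True
        df = df.loc[keep]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# flight truncation
# ---------------------------------------------------------------------------

@dataclass
class DepartureEstimate:
    """Back-projected departure window (whole UTC hour containing it)."""

    window_start: pd.Timestamp
    window_end: pd.Timestamp
    first_offshore_time: pd.Timestamp


def truncate_flight(
    fixes: pd.DataFrame,
    coastline: Coastline,
    departure_heading_tol_deg: float = 90.0,
    departure_speed_min_ms: float = 5.0,
    landfall_min_lat: float = 20.0,
) -> tuple[pd.DataFrame, DepartureEstimate | None]:
    """Slice a cleaned track to the nonstop flight.

    The flight starts at the first offshore fix whose heading lies within
    ``departure_heading_tol_deg`` of due north and whose ground speed is at
    least ``departure_speed_min_ms`` (directional departure), and ends at the
    first onshore fix at or north of ``landfall_min_lat`` (the post-crossing
    landfall).  Tracks that end mid-ocean are retained as partial tracks.
    The departure time window is estimated by back-projecting the straight-
    line distance from the last onshore fix at the departure ground speed,
    rounded outward to the containing hour.
    """
    df = _check_fixes(fixes)
    if len(df) < 2:
        raise ValueError("cannot truncate a track with fewer than 2 fixes")
    onshore = coastline.onshore(df["lat"], df["lon"])
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    dt_s = df["time"].diff().dt.total_seconds().to_numpy()[1:]
    d_km = great_circle_distance_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    gs = d_km * 1000.0 / dt_s  # speed of fix i over segment i -> i+1
    hdg = initial_bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])

    start = None
    for i in range(len(df) - 1):
        if onshore[i] or d_km[i] <= 0:
            continue
        if gs[i] >= departure_speed_min_ms and np.rad2deg(
            angular_difference(hdg[i], 0.0)
        ) <= departure_heading_tol_deg:
            start = i
            break
    if start is None:
        raise ValueError("no offshore directional fix found; empty track")

    end = len(df) - 1
    for j in range(start + 1, len(df)):
        if onshore[j] and lat[j] >= landfall_min_lat:
            end = j
            break

    departure = None
    prior_onshore = [k for k in range(start) if onshore[k]]
    if prior_onshore:
        k = prior_onshore[-1]
        d0 = great_circle_distance_deg(lat[k], lon[k], lat[start], lon[start])
        back_h = d0 * 1000.0 / gs[start] / 3600.0
        t0 = df["time"].iloc[start] - pd.Timedelta(hours=float(back_h))
        window_start = t0.floor("h")
        departure = DepartureEstimate(
            window_start=window_start,
            window_end=window_start + pd.Timedelta(hours=1),
            first_offshore_time=df["time"].iloc[start],
        )
    return df.iloc[start : end + 1].reset_index(drop=True), departure


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def compute_kinematics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-consecutive-pair segments: distance, speed, heading, turning angle.

    One segment per consecutive fix pair.  Headings are great-circle initial
    bearings and are NaN (flagged) when the pair is coincident.  Turning
    angle is the signed change in heading from the previous segment.
    """
    df = _check_fixes(fixes)
    if len(df) < 2:
        raise ValueError("kinematics require at least 2 fixes")
    dt_s = df["time"].diff().dt.total_seconds().to_numpy()[1:]
    if (dt_s <= 0).any():
        raise ValueError("duplicate or non-increasing timestamps")
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    d_km = great_circle_distance_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    heading = initial_bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    heading = np.where(d_km > 0, heading, np.nan)
    turn = np.full_like(heading, np.nan)
    for i in range(1, len(heading)):
        if np.isnan(heading[i]) or np.isnan(heading[i - 1]):
            continue
        t = np.rad2deg(angular_difference(heading[i - 1], heading[i]))
        turn[i] = t * (signed_rotation(heading[i - 1], heading[i]) or 1)
    seg = pd.DataFrame(
        {
            "id": df["id"].to_numpy()[:-1],
            "t_start": df["time"].to_numpy()[:-1],
            "t_end": df["time"].to_numpy()[1:],
            "lat1": lat[:-1],
            "lon1": lon[:-1],
            "lat2": lat[1:],
            "lon2": lon[1:],
            "dt_h": dt_s / 3600.0,
            "distance_km": d_km,
            "ground_speed_ms": d_km * 1000.0 / dt_s,
            "heading_deg": heading,
            "turn_angle_deg": turn,
        }
    )
    return seg


# ---------------------------------------------------------------------------
# Movebank-style CSV I/O and the full cascade
# ---------------------------------------------------------------------------

MOVEBANK_COLUMNS = {
    "individual-local-identifier": "id",
    "timestamp": "time",
    "location-lat": "lat",
    "location-long": "lon",
    "argos:lc": "quality",
}

_LC_MAP = {"3": "A3", "2": "A2", "1": "A1", "0": "A0", "A": "AA", "B": "AB",
           "G": "GPS", "GPS": "GPS"}


def read_movebank(path) -> pd.DataFrame:
    """Read a Movebank-style CSV into the internal fix table."""
    raw = pd.read_csv(path, dtype={"argos:lc": str})
    missing = [c for c in MOVEBANK_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"Movebank CSV missing columns {missing}")
    df = raw.rename(columns=MOVEBANK_COLUMNS)[FIX_COLUMNS[:4] + ["quality"]]
    df["time"] = pd.to_datetime(df["time"], utc=True).dt.tz_localize(None)
    df["quality"] = [_LC_MAP.get(str(q), str(q)) for q in df["quality"]]
    df = df.sort_values(["id", "time"], kind="stable").reset_index(drop=True)
    return _check_fixes(df)


def write_movebank(df: pd.DataFrame, path) -> None:
    inv = {v: k for k, v in MOVEBANK_COLUMNS.items()}
    out = df.rename(columns=inv)
    out.to_csv(path, index=False)


@dataclass
class PrepReport:
    """Counts removed per cleaning rule, per animal."""

    n_input: int = 0
    n_rate_redundancy: int = 0
    n_stopover: int = 0
    n_thin_degap: int = 0
    n_truncated: int = 0
    n_output: int = 0
    departures: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["departures"] = {
            k: None if v is None else str(v.window_start) for k, v in self.departures.items()
        }
        return d


def prepare_tracks(
    fixes: pd.DataFrame,
    coastline: Coastline,
    max_speed_kmh: float = 130.0,
    max_redundant_km: float = 5.0,
    stopover_speed_ms: float = 3.0,
    stopover_dist_km: float = 15.0,
    max_gap_h: float = 12.0,
    landfall_min_lat: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PrepReport]:
    """Run the full cleaning cascade per animal and concatenate the results."""
    df = _check_fixes(fixes)
    report = PrepReport(n_input=len(df))
    out = []
    rng = np.random.default_rng(seed)
    for animal, grp in df.groupby("id", sort=False):
        g = grp.reset_index(drop=True)
        g1 = rate_redundancy_filter(g, max_speed_kmh, max_redundant_km)
        report.n_rate_redundancy += len(g) - len(g1)
        g2 = remove_stopovers(
            g1, coastline, speed_min_ms=stopover_speed_ms, dist_min_km=stopover_dist_km
        )
        report.n_stopover += len(g1) - len(g2)
        g3 = thin_and_degap(g2, max_gap_h=max_gap_h, seed=rng)
        report.n_thin_degap += len(g2) - len(g3)
        try:
            g4, dep = truncate_flight(g3, coastline, landfall_min_lat=landfall_min_lat)
        except ValueError as exc:
            warnings.warn(f"track {animal}: {exc}; dropped")
            continue
        report.n_truncated += len(g3) - len(g4)
        report.departures[str(animal)] = dep
        out.append(g4)
    result = (
        pd.concat(out, ignore_index=True)
        if out
        else df.iloc[:0].reset_index(drop=True)
    )
    report.n_output = len(result)
    return result, report
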