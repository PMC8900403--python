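"""Downstream statistics for classified migration tracks.

Covers the band-wise circular summaries (mean direction, resultant length,
Rayleigh uniformity test), the behavior-by-latitude-band contingency analysis
(Pearson chi-square with adjusted standardized residuals and a Bonferroni
cell criterion), the wind-movement regressions and total-drift ratio
(lateral-slope over forward-slope), ground-speed model selection across
altitude policies by AICc, and the coastal-crossover displacement analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .coast import Coastline
from .corridor import Corridor, preferred_range
from .geo import GeoPoint, great_circle_path
from .wind import AltitudePolicy, SEVEN_POLICIES, wind_support

#: Default ~10-degree latitudinal bands spanning the flight corridor,
#: half-open [south, north) except the last.
DEFAULT_BANDS = ((-43, -30), (-30, -20), (-20, -10), (-10, 0), (0, 10),
                 (10, 20), (20, 30))

__all__ = [
    "DEFAULT_BANDS",
    "circular_mean_resultant",
    "rayleigh_test",
    "assign_bands",
    "band_stats",
    "bonferroni_critical",
    "behavior_band_test",
    "ContingencyResult",
    "drift_regression",
    "DriftRegression",
    "compute_movement_rates",
    "groundspeed_model_selection",
    "crossover_analysis",
]


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def circular_mean_resultant(directions_deg) -> tuple[float, float]:
    """Circular mean direction (deg) and mean resultant length of a sample.

    The mean direction is NaN (flagged) when the resultant length is zero.
    """
    d = np.deg2rad(np.asarray(directions_deg, dtype=float))
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no defined directions")
    c, s = np.cos(d).mean(), np.sin(d).mean()
    rbar = float(np.hypot(c, s))
    theta = float(np.rad2deg(np.arctan2(s, c)) % 360.0) if rbar > 1e-12 else np.nan
    return theta, rbar


def rayleigh_test(directions_deg) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    Uses Z = n * Rbar^2 with the standard series approximation

        p = exp(-Z) [1 + (2Z - Z^2)/(4n)
                       - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    clamped to (0, 1] (the series can exceed 1 at small Z).  Requires n >= 4.
    """
    d = np.asarray(directions_deg, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 4:
        raise ValueError("Rayleigh test requires at least 4 directions")
    _, rbar = circular_mean_resultant(d)
    z = n * rbar**2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def assign_bands(lats, bands=DEFAULT_BANDS):
    """Band label per latitude ('[-43,-30)' style); NaN outside all bands.
    The northernmost band is closed at its upper edge."""
    lats = np.asarray(lats, dtype=float)
    out = np.full(lats.shape, None, dtype=object)
    for i, (lo, hi) in enumerate(bands):
        closed_top = i == len(bands) - 1
        m = (lats >= lo) & ((lats <= hi) if closed_top else (lats < hi))
        out[m] = f"[{lo},{hi})"
    return out


def band_stats(
    df: pd.DataFrame,
    dir_col: str,
    speed_col: str | None = None,
    lat_col: str = "lat1",
    bands=DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-band circular summaries: mean direction, resultant length, scalar
    speed mean +/- sd, sample size and Rayleigh p."""
    work = df.copy()
    work["band"] = assign_bands(work[lat_col], bands)
    rows = []
    for lo, hi in bands:
        key = f"[{lo},{hi})"
        sub = work[work["band"] == key]
        dirs = sub[dir_col].dropna()
        if dirs.empty:
            continue
        theta, rbar = circular_mean_resultant(dirs)
        row = {
            "band": key,
            "n": len(dirs),
            "theta_bar": theta,
            "rbar": rbar,
            "circ_sd_rad": math.sqrt(-2.0 * math.log(rbar)) if rbar > 0 else np.inf,
            "rayleigh_p": rayleigh_test(dirs) if len(dirs) >= 4 else np.nan,
        }
        if speed_col is not None:
            row["speed_mean"] = float(sub[speed_col].mean())
            row["speed_sd"] = float(sub[speed_col].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency analysis
# ---------------------------------------------------------------------------

def bonferroni_critical(
    alpha_family: float, n_cells: int, two_sided: bool = False
) -> tuple[float, float]:
    """Family-wise alpha divided across cells, and the matching normal
    critical value.  The default one-sided convention reproduces the
    conventional printed pair (0.05, 35) -> (alpha ~ 0.0014, z ~ 2.98); set
    ``two_sided=True`` for the stricter convention (~ 3.19 for that pair)."""
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must be in (0, 1)")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    alpha_adj = alpha_family / n_cells
    q = 1.0 - (alpha_adj / 2.0 if two_sided else alpha_adj)
    return alpha_adj, float(sps.norm.ppf(q))


@dataclass
class ContingencyResult:
    """Omnibus chi-square test plus cell-wise adjusted standardized residuals."""

    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    cramers_v: float
    adj_residuals: pd.DataFrame
    sig_mask: pd.DataFrame
    alpha_adj: float
    z_crit: float
    n: int


def behavior_band_test(
    labeled: pd.DataFrame,
    band_col: str = "band",
    label_col: str = "behavior",
    exclude: tuple = ("overdrift",),
    alpha_family: float = 0.05,
    two_sided: bool = False,
) -> ContingencyResult:
    """Test independence of behavior and latitudinal band.

    Rare categories in ``exclude`` (overdrift by default) are dropped before
    testing.  Cells are flagged significant when the absolute adjusted
    standardized residual r_ij = (O-E)/sqrt(E(1-row/n)(1-col/n)) meets the
    Bonferroni-adjusted normal critical value.
    """
    sub = labeled.dropna(subset=[band_col, label_col])
    sub = sub[~sub[label_col].isin(exclude)]
    table = pd.crosstab(sub[band_col], sub[label_col])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 bands and >= 2 behaviors after exclusion")
    obs = table.to_numpy(dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if (expected == 0).any():
        warnings.warn("zero expected count in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    v = math.sqrt(chi2 / (n * (min(obs.shape) - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * (1.0 - row / n) * (1.0 - col / n))
        resid = np.where(denom > 0, (obs - expected) / denom, np.nan)
    alpha_adj, z_crit = bonferroni_critical(alpha_family, obs.size, two_sided)
    resid_df = pd.DataFrame(resid, index=table.index, columns=table.columns)
    return ContingencyResult(
        table=table,
        chi2=float(chi2),
        df=int(dof),
        p=float(p),
        cramers_v=float(v),
        adj_residuals=resid_df,
        sig_mask=resid_df.abs() >= z_crit,
        alpha_adj=alpha_adj,
        z_crit=z_crit,
        n=int(n),
    )


# ---------------------------------------------------------------------------
# wind-movement regressions and total drift
# ---------------------------------------------------------------------------

def compute_movement_rates(segments: pd.DataFrame, corridor: Corridor) -> pd.DataFrame:
    """Add forward/lateral movement rates relative to the preferred direction.

    ``r_v`` is the ground-velocity component along the preferred-range
    midpoint bearing at the segment start, ``r_u`` the component along its
    rightward normal; ``pref_dir`` records the midpoint bearing used.
    """
    out = segments.copy()
    pref, r_v, r_u = [], [], []
    for row in out.itertuples(index=False):
        start = GeoPoint(row.lat1, row.lon1)
        if start.lat >= corridor.band_lat or not np.isfinite(row.heading_deg):
            pref.append(np.nan), r_v.append(np.nan), r_u.append(np.nan)
            continue
        d = preferred_range(start, corridor).d_mid
        delta = np.deg2rad(row.heading_deg - d)
        pref.append(d)
        r_v.append(row.ground_speed_ms * math.cos(delta))
        r_u.append(row.ground_speed_ms * math.sin(delta))
    out["pref_dir"] = pref
    out["r_v"] = r_v
    out["r_u"] = r_u
    return out


@dataclass
class DriftRegression:
    """Forward and lateral wind-response slopes and the total-drift ratio."""

    beta_ws: float
    beta_cw: float
    intercept_forward: float
    intercept_lateral: float
    drift_ratio: float
    forward_result: object = field(repr=False, default=None)
    lateral_result: object = field(repr=False, default=None)
    lateral_residuals: np.ndarray = field(repr=False, default=None)


def _ols(y, x, groups=None):
    """OLS of y on x, optionally with fixed per-group intercepts."""
    X = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    if groups is not None:
        dummies = pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float)
        X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def drift_regression(
    segments: pd.DataFrame, group_col: str | None = None
) -> DriftRegression:
    """Fit r_v ~ ws and r_u ~ cw and report the total-drift ratio.

    A ratio of 0 marks full compensation (lateral movement insensitive to
    crosswind); 1 marks full drift (ground velocity = air vector + wind).
    """
    df = segments.dropna(subset=["r_v", "r_u", "ws", "cw"])
    if len(df) < 3:
        raise ValueError("drift regression needs at least 3 segments")
    for col in ("ws", "cw"):
        if float(np.std(df[col])) == 0.0:
            raise ValueError(f"degenerate predictor variance in {col!r}")
    groups = df[group_col] if group_col else None
    fwd = _ols(df["r_v"], df["ws"], groups)
    lat = _ols(df["r_u"], df["cw"], groups)
    beta_ws = float(fwd.params["x"])
    beta_cw = float(lat.params["x"])
    if beta_ws == 0.0:
        raise ValueError("drift ratio undefined: zero forward slope")
    return DriftRegression(
        beta_ws=beta_ws,
        beta_cw=beta_cw,
        intercept_forward=float(fwd.params["const"]),
        intercept_lateral=float(lat.params["const"]),
        drift_ratio=beta_cw / beta_ws,
        forward_result=fwd,
        lateral_result=lat,
        lateral_residuals=np.asarray(lat.resid),
    )


# ---------------------------------------------------------------------------
# ground-speed model selection across altitude policies
# ---------------------------------------------------------------------------

def _aicc(result, n: int) -> float:
    k = len(result.params) + 1  # coefficients plus residual variance
    if n <= k + 1:
        raise ValueError("AICc undefined: n <= k + 1")
    aic = -2.0 * result.llf + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def policy_wind_support(seg: pd.DataFrame, policy: AltitudePolicy) -> np.ndarray:
    """Per-segment wind support under an altitude policy.

    Expects per-level wind columns ``u_<level>``/``v_<level>``, the realized
    direction in ``heading_deg`` and the preferred direction in ``pref_dir``.
    The policy's reference direction chooses the level; the support returned
    is toward the realized travel direction (the quantity that drives ground
    speed).
    """
    ref = seg["pref_dir"] if policy.direction == "preferred" else seg["heading_deg"]
    ref = ref.to_numpy(dtype=float)
    track = seg["heading_deg"].to_numpy(dtype=float)
    cand = policy.candidate_levels
    sel = np.vstack(
        [
            wind_support(seg[f"u_{lev}"], seg[f"v_{lev}"], ref)
            for lev in sorted(cand, reverse=True)
        ]
    )
    best = np.argmax(sel, axis=0)  # first (lowest-altitude) argmax wins ties
    levs = sorted(cand, reverse=True)
    out = np.empty(len(seg))
    for i, b in enumerate(best):
        lev = levs[b]
        out[i] = wind_support(seg[f"u_{lev}"].iloc[i], seg[f"v_{lev}"].iloc[i], track[i])
    return out


def groundspeed_model_selection(
    segments: pd.DataFrame,
    policies=SEVEN_POLICIES,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Rank altitude policies by AICc of ground_speed ~ wind_support.

    Returns one row per policy sorted by AICc with columns ``policy``,
    ``aicc``, ``delta_aicc``, ``slope``, ``intercept`` (the intercept is the
    implied airspeed at zero wind support), ``n_selectable`` and ``selected``
    (True for the winner).  Among policies within delta AICc < 2 of the best,
    the one with the fewest selectable levels wins.
    """
    df = segments.dropna(subset=["ground_speed_ms", "heading_deg", "pref_dir"])
    n = len(df)
    rows = []
    for pol in policies:
        ws = policy_wind_support(df, pol)
        res = _ols(df["ground_speed_ms"], ws, df[group_col] if group_col else None)
        rows.append(
            {
                "policy": pol.label(),
                "aicc": _aicc(res, n),
                "slope": float(res.params["x"]),
                "intercept": float(res.params["const"]),
                "r2": float(res.rsquared),
                "n_selectable": pol.n_selectable,
            }
        )
    out = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].iloc[0]
    close = out[out["delta_aicc"] < 2.0]
    winner = close.sort_values(["n_selectable", "aicc"], kind="stable").index[0]
    out["selected"] = False
    out.loc[winner, "selected"] = True
    return out


# ---------------------------------------------------------------------------
# coastal crossover displacement
# ---------------------------------------------------------------------------

@dataclass
class CrossoverResult:
    """Per-track crossover longitudes/displacements and the crosswind regression."""

    per_track: pd.DataFrame
    reference_lon: float
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None
    p: float | None = None


def crossover_analysis(
    tracks: dict[str, pd.DataFrame],
    corridor: Corridor,
    coastline: Coastline,
    departure: GeoPoint,
    mean_crosswind: dict[str, float] | None = None,
    onshore_max_km: float = 10.0,
    min_lat: float = 20.0,
) -> CrossoverResult:
    """Longitudinal displacement at the coastal crossover, per track.

    The crossover is the first onshore fix within ``onshore_max_km`` of the
    coast or, failing that, the intersection of the track polyline with the
    coastline.  Displacement is measured against the crossover longitude of
    the great-circle reference route from ``departure`` to the corridor
    midpoint.  With ``mean_crosswind`` supplied (track-mean crosswind over
    all preceding locations), the displacement is regressed on it by OLS.
    Only the destination coast counts: fixes and crossings south of
    ``min_lat`` (e.g. the departure landmass) are ignored.
    """
    path = great_circle_path(departure, corridor.midpoint, n=512)
    path = path[path[:, 0] >= min_lat]
    ref = coastline.first_crossing(path[:, 0], path[:, 1])
    if ref is None:
        raise ValueError("reference great-circle route never crosses the coastline")
    ref_lat, ref_lon = ref

    rows = []
    for tid, tr in tracks.items():
        lat = tr["lat"].to_numpy(dtype=float)
        lon = tr["lon"].to_numpy(dtype=float)
        north = lat >= min_lat
        onshore = coastline.onshore(lat, lon) & north
        cross = None
        for i in np.where(onshore)[0]:
            if coastline.distance_km(lat[i], lon[i]) <= onshore_max_km:
                cross = (lat[i], lon[i])
                break
        if cross is None and north.any():
            cross = coastline.first_crossing(lat[north], lon[north])
        if cross is None:
            warnings.warn(f"track {tid} never crosses the coastline; excluded")
            continue
        rows.append(
            {
                "id": tid,
                "cross_lat": cross[0],
                "cross_lon": cross[1],
                "delta_lon": cross[1] - ref_lon,
            }
        )
    per_track = pd.DataFrame(rows)
    result = CrossoverResult(per_track=per_track, reference_lon=ref_lon)
    if mean_crosswind is not None and len(per_track) >= 3:
        per_track["mean_cw"] = [mean_crosswind.get(t, np.nan) for t in per_track["id"]]
        sub = per_track.dropna(subset=["mean_cw"])
        if len(sub) >= 3:
            fit = _ols(sub["delta_lon"], sub["mean_cw"])
            result.slope = float(fit.params["x"])
            result.intercept = float(fit.params["const"])
            result.r2 = float(fit.rsquared)
            result.p = float(fit.pvalues["x"])
    return result
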