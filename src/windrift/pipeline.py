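"""End-to-end orchestration: simulate a demo dataset, or run the full
prepare -> annotate -> corridor -> classify -> stats cascade from one config.

Every artifact is a plain text file (CSV/JSON/YAML/NetCDF for the wind grid);
identical config + seed produces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, routestats, simulate, trackprep, wind
from .coast import Coastline
from .config import RunConfig, ScenarioConfig
from .corridor import Corridor, estimate_corridor
from .geo import GeoPoint

log = logging.getLogger("windrift")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def simulate_dataset(cfg: ScenarioConfig, outdir) -> dict:
    """Write the bundled synthetic demo dataset.

    Produces tracks.csv (observed fixes), wind.nc, truth.csv (true tracks
    with generating modes), coastline.geojson and corridor.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    scenario = simulate.default_scenario(seed=cfg.seed, n_hours=cfg.n_hours,
                                         resolution_deg=cfg.resolution_deg)
    grid = simulate.generate_wind_grid(scenario)
    grid.to_netcdf(out / "wind.nc")

    coastline, geo_doc = simulate.synthetic_coastline()
    with open(out / "coastline.geojson", "w") as fh:
        json.dump(geo_doc, fh, indent=2)

    corridor = simulate.default_corridor()
    corridor.to_json(out / "corridor.json")

    modes = list(cfg.mode_weights)
    weights = np.array([cfg.mode_weights[m] for m in modes], dtype=float)
    weights /= weights.sum()

    fixes_all, truth_all = [], []
    for k in range(cfg.n_agents):
        mode = modes[int(rng.choice(len(modes), p=weights))]
        policy = simulate.AgentPolicy(
            mode=mode,
            airspeed=cfg.airspeed,
            drift_fraction=cfg.partial_fraction if mode == "partial" else 0.0,
        )
        start = GeoPoint(
            cfg.start_lat + (rng.random() - 0.5) * cfg.start_jitter_deg,
            cfg.start_lon + (rng.random() - 0.5) * cfg.start_jitter_deg,
        )
        track = simulate.simulate_agent(
            policy, grid, start, corridor,
            seed=int(rng.integers(2**31 - 1)),
            stop_lat=cfg.stop_lat,
            max_steps=cfg.n_hours - 1,
            hold_h=cfg.post_landfall_hold_h,
        )
        track.insert(0, "id", f"bird{k:02d}")
        truth_all.append(track)
        sampling = (
            simulate.GpsSampling()
            if rng.random() < cfg.gps_fraction
            else simulate.ArgosSampling()
        )
        fixes = simulate.observe(track, sampling, animal_id=f"bird{k:02d}",
                                 seed=int(rng.integers(2**31 - 1)))
        fixes_all.append(fixes)

    if fixes_all:
        fixes = pd.concat(fixes_all, ignore_index=True)
        truth = pd.concat(truth_all, ignore_index=True)
    else:
        fixes = pd.DataFrame(columns=trackprep.FIX_COLUMNS)
        truth = pd.DataFrame(columns=["id", "time", "lat", "lon", "true_mode"])
    trackprep.write_movebank(fixes, out / "tracks.csv")
    truth.to_csv(out / "truth.csv", index=False)
    cfg.to_yaml(out / "scenario.yaml")
    return {
        "tracks": str(out / "tracks.csv"),
        "wind": str(out / "wind.nc"),
        "truth": str(out / "truth.csv"),
        "coastline": str(out / "coastline.geojson"),
        "corridor": str(out / "corridor.json"),
    }


def run(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns paths of the written artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # ---- load inputs ------------------------------------------------------
    try:
        fixes = trackprep.read_movebank(cfg.tracks_path)
        coastline = Coastline.from_geojson(cfg.coastline_path)
    except (OSError, ValueError) as exc:
        raise StageError("load", str(exc))

    # ---- prepare ----------------------------------------------------------
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean, report = trackprep.prepare_tracks(
                fixes,
                coastline,
                max_speed_kmh=cfg.max_speed_kmh,
                max_redundant_km=cfg.max_redundant_km,
                stopover_speed_ms=cfg.stopover_speed_ms,
                stopover_dist_km=cfg.stopover_dist_km,
                max_gap_h=cfg.max_gap_h,
                landfall_min_lat=cfg.landfall_min_lat,
                seed=cfg.seed,
            )
    except ValueError as exc:
        raise StageError("prepare", str(exc))
    counts["prepare"] = report.as_dict()
    if clean.empty:
        raise StageError("prepare", "no tracks survived cleaning")

    # ---- corridor ---------------------------------------------------------
    try:
        if cfg.corridor_path:
            corridor = Corridor.from_json(cfg.corridor_path)
        else:
            tracks = [g for _, g in clean.groupby("id", sort=False)]
            corridor = estimate_corridor(tracks, cfg.candidate_lats)
    except (OSError, ValueError) as exc:
        raise StageError("corridor", str(exc))
    corridor.to_json(out / "corridor.json")

    # ---- kinematics + wind annotation ------------------------------------
    if not cfg.wind_path:
        raise StageError("annotate", "config missing wind path")
    try:
        grid = (
            wind.WindGrid.from_csv(cfg.wind_path)
            if str(cfg.wind_path).endswith(".csv")
            else wind.WindGrid.from_netcdf(cfg.wind_path)
        )
    except (OSError, ValueError) as exc:
        raise StageError("annotate", str(exc))
    seg_all = []
    for animal, grp in clean.groupby("id", sort=False):
        if len(grp) < 2:
            continue
        seg = trackprep.compute_kinematics(grp.reset_index(drop=True))
        seg_all.append(seg)
    if not seg_all:
        raise StageError("annotate", "no segments to annotate")
    segments = pd.concat(seg_all, ignore_index=True)
    try:
        segments = wind.annotate_segments(
            segments, grid, corridor, cfg.altitude_policy
        )
    except ValueError as exc:
        raise StageError("annotate", str(exc))
    counts["segments"] = int(len(segments))

    # ---- classify ---------------------------------------------------------
    tol = behavior.Tolerances(cfg.tau1, cfg.tau2)
    labeled = behavior.classify_track(segments, corridor, tol)
    bands = [tuple(b) for b in cfg.bands]
    labeled["band"] = routestats.assign_bands(labeled["lat1"], bands)
    labeled = routestats.compute_movement_rates(labeled, corridor)
    labeled.to_csv(out / "labeled_segments.csv", index=False)
    counts["classified"] = int(labeled["behavior"].notna().sum())
    counts["skipped"] = int(labeled.attrs.get("n_skipped", 0))

    # ---- statistics --------------------------------------------------------
    stats_out: dict = {}
    wind_bands = routestats.band_stats(labeled, "wind_dir", "wind_speed", bands=bands)
    move_bands = routestats.band_stats(labeled, "heading_deg", "ground_speed_ms",
                                       bands=bands)
    band_table = wind_bands.merge(move_bands, on="band", suffixes=("_wind", "_move"))
    band_table.to_csv(out / "band_stats.csv", index=False)

    try:
        cont = routestats.behavior_band_test(
            labeled, exclude=tuple(cfg.exclude_behaviors),
            alpha_family=cfg.alpha_family,
        )
        stats_out["contingency"] = {
            "chi2": cont.chi2, "df": cont.df, "p": cont.p,
            "cramers_v": cont.cramers_v, "n": cont.n,
            "alpha_adj": cont.alpha_adj, "z_crit": cont.z_crit,
            "table": cont.table.to_dict(),
            "adj_residuals": cont.adj_residuals.round(4).to_dict(),
        }
    except ValueError as exc:
        stats_out["contingency"] = {"error": str(exc)}

    try:
        dr = routestats.drift_regression(labeled, group_col="id")
        stats_out["drift"] = {
            "beta_ws": dr.beta_ws, "beta_cw": dr.beta_cw,
            "drift_ratio": dr.drift_ratio,
            "airspeed_intercept": dr.intercept_forward,
        }
    except ValueError as exc:
        stats_out["drift"] = {"error": str(exc)}

    try:
        ranking = routestats.groundspeed_model_selection(labeled)
        stats_out["altitude_models"] = ranking.round(4).to_dict(orient="records")
    except ValueError as exc:
        stats_out["altitude_models"] = {"error": str(exc)}

    try:
        tracks_by_id = {str(a): g for a, g in clean.groupby("id", sort=False)}
        mean_cw = {
            str(a): float(g["cw"].mean())
            for a, g in labeled.groupby("id", sort=False)
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xo = routestats.crossover_analysis(
                tracks_by_id, corridor, coastline,
                GeoPoint(cfg.departure_lat, cfg.departure_lon),
                mean_crosswind=mean_cw,
            )
        stats_out["crossover"] = {
            "reference_lon": xo.reference_lon,
            "n_tracks": int(len(xo.per_track)),
            "slope": xo.slope, "r2": xo.r2, "p": xo.p,
        }
    except ValueError as exc:
        stats_out["crossover"] = {"error": str(exc)}

    with open(out / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, default=float)

    run_log = {"config": json.loads(json.dumps(cfg.__dict__, default=str)),
               "counts": counts}
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)

    return {
        "labeled_segments": str(out / "labeled_segments.csv"),
        "band_stats": str(out / "band_stats.csv"),
        "stats": str(out / "stats.json"),
        "corridor": str(out / "corridor.json"),
        "run_log": str(out / "run_log.json"),
    }
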