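# windrift

Wind drift vs. compensation analysis for long nonstop migratory flights.

Birds crossing large ecological barriers — open ocean, deserts, gulfs —
constantly trade off following the wind (cheap, but displacing) against
holding course (safe, but costly). `windrift` implements a full analysis
chain for quantifying these in-flight behaviors from satellite telemetry and
gridded reanalysis winds: track cleaning, wind annotation with flight-altitude
selection, a circular six-behavior classifier built around a *range of
preferred directions* rather than a single goal point, and the downstream
statistics (band-wise circular summaries, behavior-by-band contingency
analysis, wind-response regressions with the total-drift ratio, and coastal
crossover displacement). A synthetic-data module generates structured wind
fields and behavioral agents with known ground truth, so every stage is
testable without any data download.

It is aimed at movement ecologists working with Argos/GPS tracks
(Movebank-style CSV) and ERA5-style pressure-level winds (NetCDF).

## The method

For each track segment three direction-only vectors are compared on the
circle: the realized travel direction **r̂** (bearing between consecutive
fixes), the wind flow direction **ŵ** = atan2(u, v) (the direction the wind
blows *toward*), and the range of preferred directions [d̂_w, d̂_e] — the
bearings from the bird's position to the western and eastern edges of its
stopover corridor, with angular midpoint d̂ and half-width θ_dd. The range
narrows with distance and widens on approach, so orientation is judged
against a region, not a point.

Wind support along a travel direction θ is the signed projection

    ws = cos(atan2(u, v) − θ) · √(u² + v²)        (positive = tailwind)

and crosswind cw is the perpendicular component (positive to the right of θ);
the decomposition conserves ws² + cw² = u² + v². The flight altitude per
location is chosen from seven pressure levels (1000…500 hPa) by a
configurable policy, by default the level with maximum wind support toward d̂
among the lower five levels (≤ 3000 m a.s.l.).

With angular separations θ_rw, θ_rd, θ_wd, θ_dd and tolerances τ₁ = 0.2 rad,
τ₂ = 0.1 rad, each segment gets exactly one label via a hierarchical decision
list:

1. θ_rw ≤ τ₁ (moving with the wind): **supported** if θ_rd ≤ θ_dd + τ₂,
   otherwise **full drift**;
2. otherwise, θ_rd ≤ θ_dd + τ₂: **full compensation**;
3. otherwise, compare rotation signs from d̂ to r̂ and from d̂ to ŵ:
   opposite signs → **overcompensation**; same side and θ_rd ≤ θ_wd →
   **partial compensation**; otherwise **overdrift**.

Downstream, the total-drift ratio β_cw/β_ws (lateral-response slope over
forward-response slope) summarizes a whole track set: 0 = full compensation,
1 = full drift.

## Worked example

Simulate 25 agents (a 50/30/20 mixture of fully compensating, partially
compensating and drifting policies) through a structured wind field — a
counter-clockwise anticyclone off the departure coast, steady trades, a calm
convergence band — observed through duty-cycled Argos and 2-h GPS tags, then
run the whole analysis:

```
windrift simulate --out demo --n-agents 25 --seed 42
windrift run --config demo_config.yaml
```

or in Python:

```python
from windrift.config import ScenarioConfig, RunConfig
from windrift.pipeline import simulate_dataset, run

paths = simulate_dataset(ScenarioConfig(n_agents=25, seed=42), "demo")
arts = run(RunConfig(tracks_path=paths["tracks"], wind_path=paths["wind"],
                     coastline_path=paths["coastline"],
                     corridor_path=paths["corridor"],
                     output_dir="demo_out", seed=1))
```

This writes five artifacts (labeled segments, band statistics, stats JSON,
corridor JSON, run log). With the seeds above the run labels 811 segments:

```
full_compensation 72.4%   full_drift 13.1%   supported 9.6%
partial_compensation 2.5% overdrift 1.6%     overcompensation 0.9%

behavior x band:  chi2(24, n=798) = 192.5, p < 0.001, Cramer's V = 0.246
drift regression: beta_ws = 0.99, beta_cw = 0.47, total drift = 0.48
crossover:        23 tracks, slope = -0.95 deg lon per m/s, p = 0.13
```

Full compensation dominates (the compensating agents are in the majority and
partial agents are often near the range), the total-drift ratio 0.48 sits
between the generating fractions, and cumulative crosswind does not
significantly predict where a track crosses the destination coast. Per-band
circular summaries (mean wind direction θ̄, resultant length R̄, scalar speed,
Rayleigh p) land in `band_stats.csv`; the calm convergence band shows up as
the drop in R̄ (0.79) and speed (2.1 m/s) in the 0–10° band.

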