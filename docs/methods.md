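# Methods

This note documents the models and procedures implemented in `windrift`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Geodesy

All distances, bearings and midpoints are computed on a sphere of radius
6371.0088 km (haversine distances, great-circle initial bearings, 3-D vector
midpoints). Ellipsoidal corrections are below 0.5% at corridor scales —
roughly two orders of magnitude below the classifier's smaller tolerance τ₂ —
so a single spherical backend is used throughout. Longitudes are normalized
to [−180, 180); all angular comparisons happen in radians internally, with
degrees only at the API boundary. Bearing differences wrap correctly across
0/360, although the study-like corridor never crosses the antimeridian.

## Track preparation

Fixes carry a quality class ordered GPS > Argos 3 > 2 > 1 > 0 > A > B.
The cleaning cascade, per animal:

1. **Rate/redundancy filter.** Any consecutive pair implying a speed above
   130 km/h loses its *later* fix (greedy forward pass, repeated to a
   fixpoint). Low-quality fixes (Argos 0/A/B) lying within 5 km of both
   temporal neighbors are removed as redundant; standard-quality and GPS
   fixes are never removed by the redundancy rule. The full state-space
   machinery of hybrid telemetry filters is deliberately not reproduced: the
   two thresholds determine a complete, workable rule set.
2. **Stopover removal.** Overland fixes whose ground speed falls below 3 m/s
   *and* whose move to the next fix is under 15 km are removed, iterated to a
   fixpoint so whole stopover clusters collapse; offshore fixes are never
   touched. Land/sea attribution is point-in-polygon against the supplied
   coastline, with a 1-km coastal buffer counted as onshore because telemetry
   error exceeds coastline precision.
3. **Thinning and de-gapping.** Within any pair of fixes closer than one
   hour the lower-quality fix is dropped; quality ties break at random with a
   recorded seed (bit-reproducible). Then any fix whose successor arrives
   more than 12 h later (strict) is removed — this deletes the fix preceding
   each tag charging gap.
4. **Flight truncation.** The flight starts at the first offshore fix whose
   heading lies within 90° of north and whose ground speed is at least 5 m/s
   (the "directional departure" rule — the criterion is necessarily an
   operationalization, and both thresholds live in the config), and ends at
   the first onshore fix at or north of a configurable landfall latitude
   (default 20° N). Tracks ending mid-ocean are kept as partial tracks.
   The departure time window is back-projected from the last onshore fix at
   the departure ground speed and reported as the containing whole hour.

All filters preserve order, never add fixes, and are idempotent.

## Wind annotation

Winds live on a regular hourly (time, level, lat, lon) grid with u (eastward)
and v (northward) in m/s at 1000, 925, 850, 775, 700, 600 and 500 hPa. The
nominal altitudes attached to these levels (100, 750, 1500, 2250, 3000, 3400,
5500 m a.s.l.) are carried as metadata only; no hypsometric computation is
done, and the 600 hPa ↔ 3400 m pairing is reproduced as given without
endorsement. Queries interpolate u and v bilinearly in latitude/longitude at
the nearest grid hour, with exact half-hour ties resolved to the *earlier*
hour (a deterministic, recorded rule).

Wind support uses the vector magnitude √(u² + v²). A published variant of
the support formula scales the projection by √(u² · v²) instead; that form
breaks the conservation identity ws² + cw² = u² + v² and is interpreted as a
typographical slip, but remains available as
`wind_support(..., magnitude="as_printed")` for audit. Crosswind is positive
to the right of the travel direction, which on a northward corridor means
positive = eastward displacement.

Altitude selection policies: `fixed(level)`, or the level maximizing wind
support toward either the preferred direction or the realized track
direction, over the lower five levels or all seven. Ties go to the lower
altitude. The default analysis policy is maximum support toward the
preferred direction over the lower five levels.

## Corridor and the range of preferred directions

The stopover corridor is estimated from tracks as the candidate latitude with
the smallest dispersion of crossing longitudes (each track's first crossing,
linearly interpolated between straddling fixes). Dispersion defaults to the
standard deviation converted to great-circle kilometers at the crossing
latitude; IQR and range are available as alternatives, and boundary
quantiles can replace the min/max for robustness studies. Ties go to the
southernmost candidate. The exact dispersion metric is a stated stand-in:
published adaptations of this idea live in supplements that vary in detail,
so the metric is pluggable and recorded in the corridor JSON.

From any point strictly south of the corridor band, the preferred range is
[d̂_w, d̂_e] — the bearings to the corridor's west and east boundary points —
with midpoint d̂ defined as the *angular midpoint of the minor arc* between
them (not, in general, the bearing to the geographic midpoint; the two agree
under symmetry) and half-width θ_dd half that arc. θ_dd grows monotonically
as the corridor approaches, which is the property the classifier relies on.

## The behavior classifier

Inputs per segment: realized direction r̂, wind flow direction ŵ, preferred
range (d̂, θ_dd), tolerances τ₁ = 0.2 rad (combined imprecision of r̂ and ŵ)
and τ₂ = 0.1 rad (imprecision of r̂ alone). τ₂ therefore pads only the range
membership test (which involves r̂ alone against a fixed range), while τ₁
gates the track–wind closeness test. The decision list is evaluated in
order; every comparison uses ≤, so boundary cases fall to the earlier rule:

1. θ_rw ≤ τ₁ → `supported` if θ_rd ≤ θ_dd + τ₂ else `full_drift`;
2. θ_rd ≤ θ_dd + τ₂ → `full_compensation`;
3. otherwise with rotation signs s_r (d̂→r̂) and s_w (d̂→ŵ):
   s_r·s_w < 0 → `overcompensation`; same side and θ_rd ≤ θ_wd →
   `partial_compensation`; else `overdrift`.

Tie conventions, made explicit because they are not derivable from the
category definitions alone: s_r = 0 cannot reach rule 3 (θ_rd = 0 always
passes rule 2); s_w = 0 (wind on the midpoint axis) gives product 0 and falls
through to the θ_rd ≤ θ_wd comparison; θ_rd = θ_wd on the same side resolves
to `partial_compensation` (r̂ = ŵ cases are already captured by rule 1).
Rotation signs are computed by wrapping the bearing difference to
(−180°, 180°] and taking its sign, with 0 at exactly 0° or 180° — a
deterministic rule immune to floating-point jitter in sin().

The classifier is total (exactly one label for every input), invariant under
joint rotation of all directions, and mirror-symmetric about d̂. An
independent brute-force reference (normalized-angle arithmetic on the unit
circle, no cross products) agrees with it on the full 1°×1° (r̂, ŵ) grid
across range half-widths {0°, 5°, 10°, 30°} — verified exhaustively in the
test suite and recomputed by the acceptance script.

Calm-wind or zero-displacement segments have undefined ŵ or r̂ and are
skipped and counted, never guessed.

## Downstream statistics

* **Band circular statistics.** The corridor is split into seven ~10°
  latitude bands. Per band: circular mean direction and mean resultant
  length R̄ of the wind-flow (and realized-direction) samples, scalar speed
  mean ± sd, and a Rayleigh uniformity test using Z = nR̄² with the standard
  series approximation for p, clamped to (0, 1] (the series exceeds 1 at
  small Z); n ≥ 4 required.
* **Behavior × band contingency.** Pearson χ² without continuity correction;
  rare `overdrift` segments are excluded by default. Effect size is
  Cramér's V. Post-hoc cell inspection uses adjusted standardized residuals
  r_ij = (O−E)/√(E(1−row/n)(1−col/n)) against a Bonferroni-adjusted normal
  critical value. The default convention is one-sided
  (α_family/cells → z via Φ⁻¹(1−α)), which for 0.05 over 35 cells gives the
  conventional (0.0014, 2.98) pair; a two-sided flag (≈ 3.19 for that pair)
  is provided.
* **Wind-response regressions and total drift.** Forward movement rate r_v
  (ground velocity projected on d̂) is regressed on wind support, lateral
  rate r_u on crosswind, by ordinary least squares with optional fixed
  per-individual intercepts. Mixed-effects machinery is intentionally
  omitted: the quantities of interest are the slopes and their ratio
  β_cw/β_ws (total drift: 0 = full compensation, 1 = full drift), and
  per-individual intercepts capture the relevant heterogeneity at these
  sample sizes. Lateral-model residuals are retained for band summaries.
  Analytic p-values are reported; bootstrap p-values are out of scope.
* **Ground-speed model selection.** Seven altitude policies (three fixed
  levels; max support over lower-5 or all-7, toward the preferred or the
  track direction) are compared by AICc of ground_speed ~ wind_support,
  with k = number of coefficients + 1 (residual variance) and
  AICc = AIC + 2k(k+1)/(n−k−1). Among models within ΔAICc < 2 of the best,
  the policy with the fewest selectable levels wins (simplicity rule). The
  fitted intercept is interpretable as the airspeed at zero wind support.
* **Crossover displacement.** The coastal crossover is the first onshore fix
  within 10 km of the coast, else the first intersection of the track
  polyline with the coastline; only the destination coast (north of a
  configurable latitude, default 20° N) counts. Displacement is the
  difference between the track's crossover longitude and that of the
  great-circle reference route from the departure point to the corridor
  midpoint, and is regressed on the track-mean crosswind. Point-to-coast
  distances use a local equirectangular metric, adequate at the ≤ 10 km
  scales where it is applied.

## Synthetic data

The generator emulates the study conditions of a trans-hemispheric,
~8,000 km south-to-north nonstop flight; it is the package's ground-truth
instrument, not a reanalysis emulator.

* **Wind fields.** Latitude-zoned regimes on a regular hourly grid:
  a counter-clockwise anticyclone (solid-body rotation, tangential speed
  0.012 m/s per km capped at 14 m/s) near the departure latitudes, steady
  trades (u, v) = (−4, 6) m/s, a calm convergence band (σ = 1.5 m/s) at
  0–10° N, weaker northern trades (−3, 4) m/s, plus node-wise Gaussian noise
  (0.8 m/s default) and optional per-level multipliers. Fields are
  deterministic given the seed. What this does *not* emulate: temporal
  evolution of synoptic systems, vertical shear structure, spatial error
  correlation — so passing recovery tests demonstrates correctness of the
  analysis chain, not robustness to every property of real reanalysis data.
* **Agents.** Airspeed defaults to 12.7 m/s (a plausible shorebird airspeed);
  one step per hour with 0.25-h flat-earth sub-steps (error vs great-circle
  stepping < 0.1% at these speeds). Modes target the classifier's
  categories: `full_compensation` offsets the heading by δ = arcsin(−c/a) to
  cancel the crosswind c (infeasible when |c| > a, in which case the agent
  crabs at ±90° and the step is flagged); `partial(f)` applies (1−f)·δ, so
  f = 0 is full compensation and f = 1 is no correction (heading = d̂ — the
  classical drift of the slope-based literature, whose lateral ground
  velocity equals the crosswind exactly); `drift` is downwind flight
  (heading = ŵ), the categorical full-drift behavior in which the realized
  direction equals the wind flow. The two drift notions are deliberately
  distinct modes: no heading choice can make a no-correction agent's
  realized direction match the wind at wind speeds that keep compensation
  feasible, so conflating them would leave the categorical ground truth
  unrecoverable. Below 2 m/s of wind a drift agent reverts to the preferred
  course (there is no flow to follow), which also prevents random-walk
  trapping in the calm band. Agents fly at a single pressure level by
  default so ground truth is unambiguous. An agent leaving the wind domain
  ends its track there (a partial track).
* **Observation.** GPS tags: a fix every 2 h with 10 m noise. Argos tags:
  a 5-h transmitting / 24-h charging duty cycle; each transmission window
  yields two location-class fixes (an early and a late satellite pass),
  reproducing a ~3.25 h within-bout reporting cadence. Class error SDs
  default to {3: 0.25, 2: 0.5, 1: 1.5, 0: 5, A: 10, B: 20} km — plausible
  published magnitudes, treated as configuration, not claims. Fixes are
  deterministic given the seed. After landfall the simulated tag keeps
  reporting from the arrival area for 48 h so that duty-cycled tags can
  capture onshore fixes, as real tags do.

## Problem sizes and numerical choices

The bundled demo uses a 2° grid (0.5° is the generator default for
analysis-scale runs), 240 hourly slices and 25 agents; recovery experiments
in the tests and the acceptance script use 20 agents per mode, 500-segment
drift-ratio fits, 2000 Rayleigh replicates of n = 50, and the full 518,400-
case classifier grid — sizes chosen so the whole suite runs in about a
minute while keeping every estimate's Monte-Carlo error well inside the
asserted bounds. Rayleigh p-values clamp to (0, 1]; regression fits refuse
degenerate predictors; contingency cells with zero expected counts are
flagged rather than silently dropped; all RNG flows from explicit seeds.

## Known limitations

* Spherical geodesy only (no ellipsoid), appropriate at the stated tolerance.
* The departure-detection rule (heading within 90° of north, ≥ 5 m/s) is an
  operationalization; alternatives would shift track starts by a fix or two.
* OLS replaces mixed models; variance components are not estimated.
* The corridor dispersion metric stands in for supplement-level detail of the
  published adaptation it follows.
* No vertical interpolation between pressure levels; no MARS/hinge-function
  modeling of continuous behavioral change; no probabilistic or smoothed
  behavior labels.
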