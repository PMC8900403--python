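"""Run configuration: every tunable of the pipeline in one YAML-able object.

Defaults follow the study conditions: a 130 km/h rate filter, 5 km redundancy
radius, 3 m/s / 15 km stopover rule, hourly thinning, 12 h gap rule,
tolerances tau1 = 0.2 rad / tau2 = 0.1 rad, and altitude selection by maximum
wind support toward the preferred direction over the lower five pressure
levels.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .routestats import DEFAULT_BANDS
from .wind import AltitudePolicy


@dataclass
class RunConfig:
    # paths
    tracks_path: str = ""
    wind_path: str = ""
    coastline_path: str = ""
    corridor_path: str = ""          # if empty, estimated from the tracks
    output_dir: str = "windrift_out"
    # track cleaning thresholds
    max_speed_kmh: float = 130.0
    max_redundant_km: float = 5.0
    stopover_speed_ms: float = 3.0
    stopover_dist_km: float = 15.0
    max_rate_per_h: float = 1.0
    max_gap_h: float = 12.0
    landfall_min_lat: float = 20.0
    # classifier tolerances (radians)
    tau1: float = 0.2
    tau2: float = 0.1
    # altitude policy
    policy_kind: str = "max_lower5"
    policy_level: int | None = None
    policy_direction: str = "preferred"
    # corridor estimation
    candidate_lats: list = field(default_factory=lambda: list(range(43, 50)))
    # analysis
    bands: list = field(default_factory=lambda: [list(b) for b in DEFAULT_BANDS])
    alpha_family: float = 0.05
    exclude_behaviors: list = field(default_factory=lambda: ["overdrift"])
    departure_lat: float = -42.5
    departure_lon: float = -73.5
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        for name in ("max_speed_kmh", "max_redundant_km", "stopover_speed_ms",
                     "stopover_dist_km", "max_rate_per_h", "max_gap_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @property
    def altitude_policy(self) -> AltitudePolicy:
        return AltitudePolicy(
            kind=self.policy_kind,
            level=self.policy_level,
            direction=self.policy_direction,
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class ScenarioConfig:
    """Configuration of the bundled synthetic demo dataset."""

    n_agents: int = 25
    seed: int = 0
    start_lat: float = -42.5
    start_lon: float = -73.5
    start_jitter_deg: float = 0.5
    stop_lat: float = 34.0
    post_landfall_hold_h: float = 48.0
    n_hours: int = 240
    resolution_deg: float = 2.0
    gps_fraction: float = 0.5
    #: generating-mode mixture over agents
    mode_weights: dict = field(default_factory=lambda: {
        "full_compensation": 0.5, "partial": 0.3, "drift": 0.2,
    })
    partial_fraction: float = 0.4
    airspeed: float = 12.7

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)
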