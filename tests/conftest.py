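import math

import numpy as np
import pandas as pd
import pytest

from windrift.corridor import Corridor
from windrift.geo import GeoPoint
from windrift.simulate import WindRegime, WindScenario, generate_wind_grid


@pytest.fixture(scope="session")
def corridor45() -> Corridor:
    """A narrow stopover corridor at 45 N (4 degrees of longitude wide)."""
    return Corridor(west=GeoPoint(45.0, -100.0), east=GeoPoint(45.0, -96.0),
                    band_lat=45.0)


def steady_wind_grid(flow_dir_deg: float, speed_ms: float, n_hours: int = 48,
                     noise_sd: float = 0.0, seed: int = 0):
    """Uniform wind blowing toward ``flow_dir_deg`` over the whole corridor."""
    u = speed_ms * math.sin(math.radians(flow_dir_deg))
    v = speed_ms * math.cos(math.radians(flow_dir_deg))
    scenario = WindScenario(
        zones=[(-46.0, 46.1, WindRegime("uniform", u=u, v=v))],
        lat_range=(-45.0, 46.0),
        lon_range=(-110.0, -60.0),
        resolution_deg=2.0,
        n_hours=n_hours,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_wind_grid(scenario)


@pytest.fixture(scope="session")
def wind_60off() -> object:
    """8 m/s wind flowing toward 60 deg, i.e. ~60 deg off a northward course."""
    return steady_wind_grid(60.0, 8.0)


def fixes_frame(times_h, lats, lons, qualities=None, animal="a1",
                t0="2021-04-10T00:00"):
    """Build a fix table from hour offsets and coordinates."""
    t0 = pd.Timestamp(t0)
    times = [t0 + pd.Timedelta(hours=float(h)) for h in times_h]
    n = len(times)
    return pd.DataFrame(
        {
            "id": [animal] * n,
            "time": times,
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
            "quality": qualities if qualities is not None else ["GPS"] * n,
        }
    )
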