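import numpy as np
import pandas as pd
import pytest

from conftest import fixes_frame
from windrift.simulate import synthetic_coastline
from windrift.trackprep import (
    compute_kinematics,
    rate_redundancy_filter,
    read_movebank,
    remove_stopovers,
    thin_and_degap,
    truncate_flight,
    write_movebank,
)

KM1 = 1 / 111.19492664455873  # one km of latitude, in degrees


@pytest.fixture(scope="module")
def coast():
    return synthetic_coastline()[0]


class TestRateRedundancy:
    def test_fast_pair_drops_later_fix(self):
        # 150 km in 1 h implies 150 km/h > 130 km/h
        df = fixes_frame([0, 1, 2], [0, 150 * KM1, 151 * KM1], [0, 0, 0])
        out = rate_redundancy_filter(df)
        assert list(out["lat"]) == [0.0, 151 * KM1]

    def test_slow_pair_kept(self):
        df = fixes_frame([0, 1], [0, 100 * KM1], [0, 0])
        assert len(rate_redundancy_filter(df)) == 2

    def test_low_quality_redundant_fix_removed(self):
        # class-B fix 3 km from both neighbors that are minutes apart
        df = fixes_frame(
            [0, 2 / 60, 4 / 60],
            [0, 3 * KM1, 0.0001],
            [0, 0, 0],
            qualities=["A3", "AB", "A3"],
        )
        out = rate_redundancy_filter(df)
        assert list(out["quality"]) == ["A3", "A3"]

    def test_good_quality_fix_not_redundant(self):
        df = fixes_frame(
            [0, 2 / 60, 4 / 60],
            [0, 3 * KM1, 0.0001],
            [0, 0, 0],
            qualities=["A3", "A2", "A3"],
        )
        assert len(rate_redundancy_filter(df)) == 3

    def test_identity_under_infinite_thresholds(self):
        rng = np.random.default_rng(0)
        df = fixes_frame(np.arange(20), rng.uniform(-5, 5, 20), rng.uniform(-5, 5, 20))
        out = rate_redundancy_filter(df, max_speed_kmh=np.inf, max_redundant_km=0.0)
        pd.testing.assert_frame_equal(out, df)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        lats = np.cumsum(rng.uniform(0, 2, 30))
        df = fixes_frame(np.arange(30), lats, np.zeros(30),
                         qualities=list(rng.choice(["A3", "A1", "AB"], 30)))
        once = rate_redundancy_filter(df)
        twice = rate_redundancy_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_single_fix_warns(self):
        df = fixes_frame([0], [0], [0])
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = rate_redundancy_filter(df)
        assert len(out) == 1


class TestStopovers:
    def test_slow_short_overland_removed(self, coast):
        # onshore at 35N (northern landmass), crawling 10 km in 2 h (1.4 m/s)
        df = fixes_frame([0, 2, 4], [35, 35 + 10 * KM1, 36], [-90, -90, -90])
        out = remove_stopovers(df, coast)
        assert len(out) == 2  # first fix removed (slow AND short)

    def test_fast_overland_kept(self, coast):
        df = fixes_frame([0, 2], [35, 35 + 100 * KM1], [-90, -90])  # ~14 m/s
        assert len(remove_stopovers(df, coast)) == 2

    def test_offshore_never_removed(self, coast):
        df = fixes_frame([0, 2, 4], [0, 10 * KM1, 1], [-90, -90, -90])  # open ocean
        assert len(remove_stopovers(df, coast)) == 3

    def test_requires_land_information(self):
        df = fixes_frame([0, 1], [0, 1], [0, 0])
        with pytest.raises(ValueError, match="coastline or onshore"):
            remove_stopovers(df)

    def test_stopover_cluster_collapses(self, coast):
        # five nearly stationary onshore fixes then a real move
        lats = [35, 35 + KM1, 35 + 2 * KM1, 35 + 3 * KM1, 35 + 4 * KM1, 36.5]
        df = fixes_frame([0, 3, 6, 9, 12, 14], lats, [-90] * 6)
        out = remove_stopovers(df, coast)
        assert len(out) == 1 or list(out["lat"])[-1] == 36.5


class TestThinDegap:
    def test_quality_preferred_within_hour(self):
        df = fixes_frame([0, 0.5, 2], [0, 0.1, 0.2], [0, 0, 0],
                         qualities=["AB", "GPS", "GPS"])
        out = thin_and_degap(df)
        assert list(out["quality"]) == ["GPS", "GPS"]

    def test_equal_quality_random_tiebreak_is_reproducible(self):
        df = fixes_frame([0, 0.5, 2], [0, 0.1, 0.2], [0, 0, 0])
        a = thin_and_degap(df, seed=42)
        b = thin_and_degap(df, seed=42)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 2

    def test_gap_rule_strict_inequality(self):
        # 13 h gap: predecessor removed; exactly 12 h: kept
        df13 = fixes_frame([0, 1.5, 14.5, 15.5], [0, 1, 2, 3], [0] * 4)
        out13 = thin_and_degap(df13)
        assert 1.0 not in out13["lat"].values  # fix before the 13 h gap dropped
        df12 = fixes_frame([0, 1.5, 13.5, 14.5], [0, 1, 2, 3], [0] * 4)
        out12 = thin_and_degap(df12)
        assert 1.0 in out12["lat"].values

    def test_consecutive_kept_fixes_at_least_one_hour_apart(self):
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0, 10, 40))
        df = fixes_frame(times, np.arange(40) * 0.01, np.zeros(40))
        out = thin_and_degap(df, seed=1)
        dts = out["time"].diff().dt.total_seconds().dropna() / 3600.0
        assert (dts >= 1.0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        times = np.sort(rng.uniform(0, 30, 50))
        df = fixes_frame(times, np.arange(50) * 0.02, np.zeros(50))
        once = thin_and_degap(df, seed=5)
        twice = thin_and_degap(once, seed=5)
        pd.testing.assert_frame_equal(once, twice)


class TestTruncate:
    def _track(self):
        # 3 onshore days (stationary at 42.5 S), then a northward flight
        pre = fixes_frame([0, 24, 48], [-42.5] * 3, [-73.5] * 3)
        hours = np.arange(50)
        flight = fixes_frame(72 + hours, -40.5 + 1.6 * hours, [-85.0] * 50)
        return pd.concat([pre, flight], ignore_index=True)

    def test_predeparture_fixes_dropped(self, coast):
        out, dep = truncate_flight(self._track(), coast)
        assert out["lat"].iloc[0] > -41.0  # offshore start
        assert dep is not None

    def test_departure_window_backprojection(self, coast):
        out, dep = truncate_flight(self._track(), coast)
        # window is the whole hour containing the back-projected departure
        assert dep.window_start <= dep.first_offshore_time
        assert (dep.window_end - dep.window_start) == pd.Timedelta(hours=1)

    def test_ends_at_first_overland_fix(self, coast):
        out, _ = truncate_flight(self._track(), coast)
        # first fix at/north of the 30 N coast ends the flight
        assert out["lat"].iloc[-1] >= 30.0
        assert (out["lat"].iloc[:-1] < 30.0).all()

    def test_partial_track_retained(self, coast):
        df = self._track()
        df = df[df["lat"] < 10].reset_index(drop=True)  # dies mid-ocean
        out, _ = truncate_flight(df, coast)
        assert len(out) > 10
        assert out["lat"].iloc[-1] == df["lat"].iloc[-1]

    def test_no_offshore_fix_raises(self, coast):
        df = fixes_frame([0, 24], [-42.5, -42.5], [-73.5, -73.5])
        with pytest.raises(ValueError, match="offshore"):
            truncate_flight(df, coast)


class TestKinematics:
    def test_known_segment(self):
        df = fixes_frame([0, 1], [0, 0], [0, 1])
        seg = compute_kinematics(df)
        assert seg["distance_km"].iloc[0] == pytest.approx(111.195, abs=1e-3)
        assert seg["ground_speed_ms"].iloc[0] == pytest.approx(30.89, abs=0.01)
        assert seg["heading_deg"].iloc[0] == pytest.approx(90.0)

    def test_stationary_pair_flagged(self):
        df = fixes_frame([0, 1], [5, 5], [5, 5])
        seg = compute_kinematics(df)
        assert seg["ground_speed_ms"].iloc[0] == 0.0
        assert np.isnan(seg["heading_deg"].iloc[0])

    def test_collinear_equatorial_turning_angle_zero(self):
        df = fixes_frame([0, 1, 2], [0, 0, 0], [0, 1, 2])
        seg = compute_kinematics(df)
        assert seg["turn_angle_deg"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_timestamps_raise(self):
        df = fixes_frame([0, 0], [0, 1], [0, 1])
        with pytest.raises(ValueError, match="timestamp"):
            compute_kinematics(df)


def test_movebank_roundtrip(tmp_path):
    df = fixes_frame([0, 3, 6], [-42, -41, -40], [-73, -74, -75],
                     qualities=["A3", "AB", "GPS"])
    path = tmp_path / "fixes.csv"
    write_movebank(df, path)
    back = read_movebank(path)
    assert list(back["quality"]) == ["A3", "AB", "GPS"]
    np.testing.assert_allclose(back["lat"], df["lat"])
    assert (back["time"] == df["time"]).all()
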