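import math

import numpy as np
import pandas as pd
import pytest

from windrift.corridor import Corridor
from windrift.geo import GeoPoint
from windrift.routestats import (
    assign_bands,
    band_stats,
    behavior_band_test,
    bonferroni_critical,
    circular_mean_resultant,
    crossover_analysis,
    drift_regression,
    groundspeed_model_selection,
    rayleigh_test,
)
from windrift.wind import PRESSURE_LEVELS


class TestCircular:
    def test_concentrated_sample(self):
        theta, rbar = circular_mean_resultant([0, 0, 0])
        assert theta == pytest.approx(0.0)
        assert rbar == pytest.approx(1.0)

    def test_uniform_cancellation(self):
        theta, rbar = circular_mean_resultant([0, 90, 180, 270])
        assert rbar == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(theta)

    def test_wraparound_mean(self):
        theta, rbar = circular_mean_resultant([350, 10])
        assert theta == pytest.approx(0.0, abs=1e-9) or theta == pytest.approx(360.0)
        assert rbar == pytest.approx(math.cos(math.radians(10)))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 360, 40)
        t0, r0 = circular_mean_resultant(d)
        t1, r1 = circular_mean_resultant((d + 77.0) % 360)
        assert r1 == pytest.approx(r0)
        assert (t1 - t0) % 360 == pytest.approx(77.0, abs=1e-9)


class TestRayleigh:
    def test_uniform_four_points_clamped_to_one(self):
        assert rayleigh_test([0, 90, 180, 270]) == 1.0

    def test_identical_directions_tiny_p(self):
        assert rayleigh_test([42.0] * 100) < 1e-10

    def test_requires_four(self):
        with pytest.raises(ValueError, match="at least 4"):
            rayleigh_test([0, 10, 20])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            if rayleigh_test(rng.uniform(0, 360, 50)) < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.08


class TestBonferroni:
    def test_printed_pair(self):
        alpha, z = bonferroni_critical(0.05, 35)
        assert alpha == pytest.approx(0.0014, abs=5e-5)
        assert z == pytest.approx(2.98, abs=0.01)

    def test_single_cell_one_sided(self):
        alpha, z = bonferroni_critical(0.05, 1)
        assert alpha == 0.05
        assert z == pytest.approx(1.645, abs=1e-3)

    def test_median_limit(self):
        _, z = bonferroni_critical(0.5, 1)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_two_sided_convention_is_stricter(self):
        _, z1 = bonferroni_critical(0.05, 35)
        _, z2 = bonferroni_critical(0.05, 35, two_sided=True)
        assert z2 > z1
        assert z2 == pytest.approx(3.19, abs=0.01)


def _labeled_frame(counts: dict, bands: list, behaviors: list):
    rows = []
    for (b, lab), k in counts.items():
        rows += [{"band": bands[b], "behavior": behaviors[lab]}] * k
    return pd.DataFrame(rows)


class TestContingency:
    def test_flat_table_gives_zero_chi2(self):
        bands, behaviors = ["s", "n"], ["x", "y"]
        counts = {(i, j): 10 for i in range(2) for j in range(2)}
        res = behavior_band_test(_labeled_frame(counts, bands, behaviors),
                                 exclude=())
        assert res.chi2 == pytest.approx(0.0)
        assert np.allclose(res.adj_residuals, 0.0)

    def test_df_for_seven_by_five_design(self):
        rng = np.random.default_rng(5)
        bands = [f"b{i}" for i in range(7)]
        behaviors = [f"beh{j}" for j in range(5)]
        counts = {(i, j): int(rng.integers(5, 30)) for i in range(7) for j in range(5)}
        res = behavior_band_test(_labeled_frame(counts, bands, behaviors),
                                 exclude=())
        assert res.df == 24

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            obs = rng.integers(1, 40, size=(3, 3)).astype(float)
            bands = ["a", "b", "c"]
            behaviors = ["x", "y", "z"]
            counts = {(i, j): int(obs[i, j]) for i in range(3) for j in range(3)}
            res = behavior_band_test(_labeled_frame(counts, bands, behaviors),
                                     exclude=())
            # brute-force expected counts, chi2 and adjusted residuals
            o = res.table.to_numpy(dtype=float)
            n = o.sum()
            chi2 = 0.0
            resid = np.zeros_like(o)
            for i in range(3):
                for j in range(3):
                    e = o[i].sum() * o[:, j].sum() / n
                    chi2 += (o[i, j] - e) ** 2 / e
                    resid[i, j] = (o[i, j] - e) / math.sqrt(
                        e * (1 - o[i].sum() / n) * (1 - o[:, j].sum() / n)
                    )
            assert res.chi2 == pytest.approx(chi2, abs=1e-9)
            assert np.allclose(res.adj_residuals.to_numpy(), resid, atol=1e-9)

    def test_overdrift_excluded_by_default(self):
        bands = ["s", "n"]
        behaviors = ["supported", "overdrift"]
        counts = {(i, j): 10 for i in range(2) for j in range(2)}
        with pytest.raises(ValueError, match=">= 2"):
            behavior_band_test(_labeled_frame(counts, bands, behaviors))


def test_assign_bands_edges():
    labels = assign_bands([-43, -30.0, -0.001, 0.0, 29.999, 30.0, 31.0])
    assert labels[0] == "[-43,-30)"
    assert labels[1] == "[-30,-20)"   # half-open at the top of each band
    assert labels[2] == "[-10,0)"
    assert labels[3] == "[0,10)"
    assert labels[5] == "[20,30)"     # northernmost band closed above
    assert labels[6] is None


def test_band_stats_columns():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "lat1": rng.uniform(-40, 29, 200),
            "wind_dir": rng.normal(350, 10, 200) % 360,
            "wind_speed": rng.uniform(2, 12, 200),
        }
    )
    out = band_stats(df, "wind_dir", "wind_speed")
    assert {"band", "n", "theta_bar", "rbar", "rayleigh_p", "speed_mean"} <= set(out)
    assert (out["rbar"] > 0.9).all()  # concentrated winds in every band
    assert (out["rayleigh_p"] < 0.01).all()


class TestDriftRegression:
    def test_exact_linear_construction(self):
        rng = np.random.default_rng(0)
        ws = rng.uniform(-5, 10, 100)
        cw = rng.uniform(-8, 8, 100)
        df = pd.DataFrame({"ws": ws, "cw": cw,
                           "r_v": 10 + 0.8 * ws, "r_u": 0.25 * cw})
        res = drift_regression(df)
        assert res.beta_ws == pytest.approx(0.8, abs=1e-9)
        assert res.intercept_forward == pytest.approx(10.0, abs=1e-9)
        assert res.drift_ratio == pytest.approx(0.25 / 0.8, abs=1e-9)

    def test_degenerate_predictor_raises(self):
        df = pd.DataFrame({"ws": [1.0] * 5, "cw": range(5),
                           "r_v": range(5), "r_u": range(5)})
        with pytest.raises(ValueError, match="degenerate"):
            drift_regression(df)

    def test_needs_three_segments(self):
        df = pd.DataFrame({"ws": [1, 2], "cw": [1, 2], "r_v": [1, 2], "r_u": [1, 2]})
        with pytest.raises(ValueError, match="at least 3"):
            drift_regression(df)


class TestModelSelection:
    def _segments(self, true_level=925, n=300, seed=0):
        rng = np.random.default_rng(seed)
        seg = pd.DataFrame({"heading_deg": np.zeros(n), "pref_dir": np.zeros(n)})
        for lev in PRESSURE_LEVELS:
            seg[f"u_{lev}"] = rng.normal(0, 4, n)
            seg[f"v_{lev}"] = rng.normal(2, 4, n)
        seg["ground_speed_ms"] = (
            12.7 + seg[f"v_{true_level}"] + rng.normal(0, 0.5, n)
        )
        return seg

    def test_recovers_generating_level(self):
        ranked = groundspeed_model_selection(self._segments(925))
        assert ranked["policy"].iloc[0] == "fixed(925)"
        assert ranked["selected"].iloc[0]
        assert ranked["intercept"].iloc[0] == pytest.approx(12.7, abs=0.2)

    def test_aicc_approaches_aic_for_large_n(self):
        # correction term 2k(k+1)/(n-k-1) vanishes as n grows
        k = 3
        n = 10**5
        assert 2 * k * (k + 1) / (n - k - 1) < 0.01

    def test_simpler_model_wins_within_two_aicc(self):
        # ground speed driven by wind common to every level: all policies fit
        # equally, so the fixed (1-level) policy must be selected
        rng = np.random.default_rng(1)
        n = 200
        seg = pd.DataFrame({"heading_deg": np.zeros(n), "pref_dir": np.zeros(n)})
        v = rng.normal(2, 4, n)
        u = rng.normal(0, 4, n)
        for lev in PRESSURE_LEVELS:
            seg[f"u_{lev}"] = u
            seg[f"v_{lev}"] = v
        seg["ground_speed_ms"] = 12.7 + v + rng.normal(0, 0.3, n)
        ranked = groundspeed_model_selection(seg)
        sel = ranked[ranked["selected"]].iloc[0]
        assert sel["n_selectable"] == 1
        assert sel["delta_aicc"] < 2.0

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError, match="AICc"):
            groundspeed_model_selection(self._segments(n=4))


@pytest.fixture(scope="module")
def coast():
    from windrift.simulate import synthetic_coastline

    return synthetic_coastline()[0]


@pytest.fixture(scope="module")
def corridor():
    return Corridor(GeoPoint(45, -100), GeoPoint(45, -96), band_lat=45)


class TestCrossover:
    def _track(self, lons, lats, tid="t0"):
        return pd.DataFrame({"id": tid, "lat": lats, "lon": lons})

    def test_zonal_coast_interpolation(self, coast, corridor):
        # track on one meridian straddling the 30 N coast
        tr = self._track([-95.0, -95.0], [29.5, 30.5])
        res = crossover_analysis({"t": tr}, corridor, coast, GeoPoint(-42.5, -73.5))
        assert res.per_track["cross_lat"].iloc[0] == pytest.approx(30.0, abs=1e-6)
        assert res.per_track["cross_lon"].iloc[0] == pytest.approx(-95.0, abs=1e-6)

    def test_reference_route_zero_displacement(self, coast, corridor):
        from windrift.geo import great_circle_path

        dep = GeoPoint(-42.5, -73.5)
        path = great_circle_path(dep, corridor.midpoint, n=200)
        tr = self._track(path[:, 1], path[:, 0])
        res = crossover_analysis({"t": tr}, corridor, coast, dep)
        assert res.per_track["delta_lon"].iloc[0] == pytest.approx(0.0, abs=0.02)

    def test_onshore_fix_near_coast_used_directly(self, coast, corridor):
        lat_8km = 30.0 + 8.0 / 111.19492664455873
        tr = self._track([-94.0, -94.2], [29.0, lat_8km])
        res = crossover_analysis({"t": tr}, corridor, coast, GeoPoint(-42.5, -73.5))
        assert res.per_track["cross_lon"].iloc[0] == pytest.approx(-94.2)
        assert res.per_track["cross_lat"].iloc[0] == pytest.approx(lat_8km)

    def test_track_never_crossing_excluded(self, coast, corridor):
        tr = self._track([-95.0, -95.0], [10.0, 25.0])
        with pytest.warns(UserWarning, match="never crosses"):
            res = crossover_analysis({"t": tr}, corridor, coast,
                                     GeoPoint(-42.5, -73.5))
        assert res.per_track.empty

    def test_mirror_antisymmetry(self, coast, corridor):
        # reflecting a scenario about the reference meridian flips delta_lon
        dep = GeoPoint(-42.5, -73.5)
        base = crossover_analysis(
            {"t": self._track([-95.0, -95.0], [29.5, 30.5])},
            corridor, coast, dep)
        ref_lon = base.reference_lon
        for off in (3.0, 7.5):
            east = crossover_analysis(
                {"t": self._track([ref_lon + off] * 2, [29.5, 30.5])},
                corridor, coast, dep)
            west = crossover_analysis(
                {"t": self._track([ref_lon - off] * 2, [29.5, 30.5])},
                corridor, coast, dep)
            d_e = east.per_track["delta_lon"].iloc[0]
            d_w = west.per_track["delta_lon"].iloc[0]
            assert d_e == pytest.approx(-d_w, abs=1e-9)
            assert d_e == pytest.approx(off, abs=1e-9)

    def test_crosswind_regression(self, coast, corridor):
        dep = GeoPoint(-42.5, -73.5)
        rng = np.random.default_rng(4)
        tracks, mean_cw = {}, {}
        for k in range(10):
            cw = rng.uniform(-5, 5)
            off = 1.2 * cw  # displacement proportional to crosswind
            tracks[f"t{k}"] = self._track([-92.5 + off] * 2, [29.5, 30.5], tid=f"t{k}")
            mean_cw[f"t{k}"] = cw
        res = crossover_analysis(tracks, corridor, coast, dep, mean_crosswind=mean_cw)
        assert res.slope == pytest.approx(1.2, abs=0.05)
        assert res.r2 > 0.95
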