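import numpy as np
import pandas as pd
import pytest
import shapely

import lionhab.trajectory as tj
from lionhab.trajectory import wrap_angle


def _track(times, xs=None, ys=None, animal="a"):
    n = len(times)
    return pd.DataFrame(
        {
            "animal_id": animal,
            "timestamp": pd.DatetimeIndex(times, tz="UTC"),
            "x": xs if xs is not None else np.zeros(n),
            "y": ys if ys is not None else np.zeros(n),
        }
    )


class TestResample:
    def test_hourly_to_12h_keeps_every_12th(self, hourly_track):
        out = tj.resample_track(hourly_track, 12.0, 120.0)
        expected = hourly_track.iloc[::12].reset_index(drop=True)
        pd.testing.assert_frame_equal(out, expected)

    def test_gap_skips_and_resumes(self):
        times = list(pd.date_range("2023-01-01", periods=13, freq="h"))
        times += list(pd.date_range("2023-01-02 18:00", periods=13, freq="h"))  # 30 h gap
        out = tj.resample_track(_track(times), 12.0, 120.0)
        kept = list(out["timestamp"].dt.strftime("%d %H"))
        assert kept == ["01 00", "01 12", "02 18", "03 06"]

    def test_single_fix_kept(self):
        out = tj.resample_track(_track(["2023-01-01"]), 12.0, 120.0)
        assert len(out) == 1

    def test_idempotent(self, hourly_track):
        once = tj.resample_track(hourly_track, 12.0, 120.0)
        twice = tj.resample_track(once, 12.0, 120.0)
        pd.testing.assert_frame_equal(once, twice)


class TestSeason:
    @pytest.mark.parametrize(
        "ts,season",
        [
            ("2023-12-15", "wet"),
            ("2023-06-01 00:00", "dry"),
            ("2023-05-31 23:59", "wet"),
            ("2023-11-30", "dry"),
        ],
    )
    def test_month_boundaries(self, ts, season):
        out = tj.annotate_season(_track([ts]))
        assert out["season"].iloc[0] == season
        assert tj.season_of(ts) == season

    def test_labels_partition_all_fixes(self, hourly_track):
        out = tj.annotate_season(hourly_track)
        assert set(out["season"]) <= {"wet", "dry"}
        assert out["season"].notna().all()


class TestClip:
    def test_inside_identity_outside_empty(self):
        poly = shapely.box(-10, -10, 10, 10)
        inside = _track(["2023-01-01", "2023-01-02"], xs=[0, 5], ys=[0, 5])
        pd.testing.assert_frame_equal(tj.clip_to_study_area(inside, poly), inside)
        outside = _track(["2023-01-01"], xs=[100], ys=[100])
        with pytest.warns(UserWarning, match="outside"):
            assert len(tj.clip_to_study_area(outside, poly)) == 0

    def test_mixed_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        poly = shapely.Polygon([(0, 0), (80, 10), (100, 100), (10, 70)])
        xs, ys = rng.uniform(-20, 120, 200), rng.uniform(-20, 120, 200)
        track = _track(pd.date_range("2023-01-01", periods=200, freq="h"), xs, ys)
        out = tj.clip_to_study_area(track, poly)
        expected = sum(poly.contains(shapely.Point(x, y)) for x, y in zip(xs, ys))
        assert len(out) == expected


class TestSteps:
    def test_two_fixes_single_step_length(self):
        track = _track(["2023-01-01 00:00", "2023-01-01 01:00"], xs=[0, 400], ys=[0, 0])
        steps = tj.build_steps(track, 1.0, 30.0)
        assert len(steps) == 1
        assert steps["step_length"].iloc[0] == pytest.approx(400.0)
        assert np.isnan(steps["turn_angle"].iloc[0])

    def test_collinear_turn_zero_and_reversal_plus_pi(self):
        times = pd.date_range("2023-01-01", periods=4, freq="h")
        steps = tj.build_steps(_track(times, xs=[0, 100, 200, 100], ys=[0, 0, 0, 0]), 1.0, 30.0)
        assert steps["turn_angle"].iloc[1] == pytest.approx(0.0)
        assert steps["turn_angle"].iloc[2] == pytest.approx(np.pi)  # +pi, never -pi

    def test_gap_breaks_burst(self):
        times = ["2023-01-01 00:00", "2023-01-01 01:00", "2023-01-01 05:00", "2023-01-01 06:00"]
        steps = tj.build_steps(_track(times, xs=[0, 100, 200, 300], ys=[0, 0, 0, 0]), 1.0, 30.0)
        assert len(steps) == 2
        assert steps["turn_angle"].isna().all()  # no contiguous predecessor

    def test_lengths_invariant_to_rigid_motion(self, hourly_track):
        steps = tj.build_steps(hourly_track, 1.0, 30.0)
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy = (hourly_track[["x", "y"]].to_numpy() @ rot.T) + [1e5, -2e5]
        moved = hourly_track.assign(x=xy[:, 0], y=xy[:, 1])
        steps2 = tj.build_steps(moved, 1.0, 30.0)
        np.testing.assert_allclose(steps2["step_length"], steps["step_length"], rtol=1e-9)
        np.testing.assert_allclose(
            wrap_angle(steps2["turn_angle"].dropna() - steps["turn_angle"].dropna()), 0.0, atol=1e-9
        )


class TestKernelFit:
    def test_gamma_recovered_within_5pct(self):
        rng = np.random.default_rng(0)
        steps = pd.DataFrame(
            {"step_length": rng.gamma(2.0, 300.0, 10_000), "turn_angle": rng.vonmises(0.0, 1.0, 10_000)}
        )
        k = tj.fit_movement_kernel(steps)
        assert k.gamma_shape == pytest.approx(2.0, rel=0.05)
        assert k.gamma_scale == pytest.approx(300.0, rel=0.05)

    def test_uniform_angles_give_tiny_kappa(self):
        rng = np.random.default_rng(1)
        steps = pd.DataFrame(
            {"step_length": rng.gamma(2.0, 300.0, 10_000), "turn_angle": rng.uniform(-np.pi, np.pi, 10_000)}
        )
        assert tj.fit_movement_kernel(steps).vm_kappa <= 0.05

    def test_concentrated_angles_hit_cap_with_flag(self):
        rng = np.random.default_rng(2)
        steps = pd.DataFrame({"step_length": rng.gamma(2.0, 300.0, 100), "turn_angle": np.zeros(100)})
        k = tj.fit_movement_kernel(steps)
        assert k.vm_kappa == pytest.approx(700.0)
        assert k.degenerate

    def test_errors_on_degenerate_input(self):
        steps = pd.DataFrame({"step_length": np.full(100, 5.0), "turn_angle": np.zeros(100)})
        with pytest.raises(ValueError, match="identical"):
            tj.fit_movement_kernel(steps)
        with pytest.raises(ValueError, match=">="):
            tj.fit_movement_kernel(steps.head(10))


class TestMSD:
    def test_stationary_zero(self):
        track = _track(pd.date_range("2023-01-01", periods=5, freq="h"), xs=np.ones(5), ys=np.ones(5))
        assert tj.mean_squared_displacement(track) == 0.0

    @pytest.mark.parametrize("n", [2, 3, 10])
    def test_straight_line_closed_form(self, n):
        d_km = 2.0
        track = _track(
            pd.date_range("2023-01-01", periods=n + 1, freq="h"),
            xs=np.arange(n + 1) * d_km * 1000,
            ys=np.zeros(n + 1),
        )
        expected = d_km**2 * n * (2 * n + 1) / 6.0
        assert tj.mean_squared_displacement(track) == pytest.approx(expected)

    def test_msd_table_reports_both_scales(self, hourly_track):
        tab = tj.msd_table(hourly_track)
        assert {"msd_km2", "rmsd_km"} <= set(tab.columns)
        np.testing.assert_allclose(tab["rmsd_km"], np.sqrt(tab["msd_km2"]))


class TestMSDSeasonModel:
    def _table(self, ratio):
        msd = np.r_[np.full(6, 40.0), np.full(6, 40.0 * ratio)]
        return pd.DataFrame({"animal_id": list(range(6)) * 2, "season": ["dry"] * 6 + ["wet"] * 6, "msd_km2": msd})

    def test_identical_seasons_coefficient_zero(self):
        res = tj.msd_season_model(self._table(1.0))
        assert res["coef_wet_vs_dry"] == pytest.approx(0.0, abs=1e-8)

    def test_exact_doubling_gives_log2(self):
        res = tj.msd_season_model(self._table(2.0))
        assert res["coef_wet_vs_dry"] == pytest.approx(np.log(2.0), abs=1e-8)
        assert res["ratio_wet_dry"] == pytest.approx(2.0, rel=1e-6)

    def test_nonpositive_msd_rejected(self):
        bad = self._table(1.0)
        bad.loc[0, "msd_km2"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            tj.msd_season_model(bad)


class TestCategories:
    def test_fix_inherits_interval_active_at_timestamp(self):
        track = _track(pd.date_range("2023-01-01", periods=4, freq="30D"))
        iv = pd.DataFrame(
            {
                "animal_id": ["a", "a"],
                "category": ["nomadic_male", "resident_male"],
                "start": pd.DatetimeIndex(["2023-01-01", "2023-02-15"], tz="UTC"),
                "end": pd.DatetimeIndex(["2023-02-15", "2023-12-31"], tz="UTC"),
            }
        )
        out = tj.assign_category(track, iv)
        assert list(out["category"]) == ["nomadic_male", "nomadic_male", "resident_male", "resident_male"]


def test_track_csv_roundtrip(tmp_path, hourly_track):
    path = tmp_path / "t.csv"
    tj.write_track_csv(hourly_track, path)
    back = tj.read_track_csv(path)
    assert (back["timestamp"] == hourly_track["timestamp"]).all()
    np.testing.assert_allclose(back["x"], hourly_track["x"])
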