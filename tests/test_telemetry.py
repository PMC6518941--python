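"""Detection cleaning, COA, day/night, DVM, home range, fate, fitness."""

import numpy as np
import pandas as pd
import pytest

from fjordflow import solar, synthdata, telemetry
from fjordflow.telemetry import CHI2_95


def _det_frame(times, depths, fish="F1", lon=8.93, lat=58.62):
    return pd.DataFrame(
        {
            "fish_id": fish,
            "timestamp": pd.DatetimeIndex(times, tz="UTC"),
            "receiver_id": "R01",
            "lon": lon,
            "lat": lat,
            "depth_m": depths,
        }
    )


class TestFalseDetectionFilter:
    def test_single_detection_day_removed(self):
        det = _det_frame(
            ["2012-06-01 10:00", "2012-06-02 10:00", "2012-06-02 11:00"], [5.0, 5.0, 5.0]
        )
        out = telemetry.filter_false_detections(det)
        assert len(out) == 2
        assert (out["timestamp"].dt.day == 2).all()

    def test_two_detections_kept(self):
        det = _det_frame(["2012-06-01 10:00", "2012-06-01 20:00"], [5.0, 5.0])
        out = telemetry.filter_false_detections(det)
        assert len(out) == 2

    def test_noise_injections_removed_track_intact(self):
        rng = np.random.default_rng(1)
        good_times = pd.date_range("2012-06-01", periods=200, freq="30min", tz="UTC")
        good = _det_frame(good_times, rng.uniform(4, 8, 200))
        noise = _det_frame(
            pd.DatetimeIndex(["2012-07-10 03:00", "2012-07-12 14:00"], tz="UTC"),
            [5.0, 5.0],
            fish="F2",
        )
        out = telemetry.filter_false_detections(pd.concat([good, noise], ignore_index=True))
        assert (out["fish_id"] == "F1").all()
        assert len(out) == 200


class TestPostMortemTruncation:
    def test_constant_tail_truncated(self):
        rng = np.random.default_rng(2)
        times = pd.date_range("2012-06-01", periods=30 * 24, freq="1h", tz="UTC")
        depths = np.concatenate([rng.uniform(4, 12, 20 * 24), np.full(10 * 24, 7.0)])
        det = _det_frame(times, depths)
        out, flags = telemetry.truncate_post_mortem(det)
        t_star = flags["F1"]
        assert t_star is not None
        truth_death = times[20 * 24]
        assert abs(t_star - truth_death) <= pd.Timedelta(hours=24)
        assert out["timestamp"].max() <= t_star

    def test_moving_fish_untouched(self):
        rng = np.random.default_rng(3)
        times = pd.date_range("2012-06-01", periods=10 * 24, freq="1h", tz="UTC")
        det = _det_frame(times, rng.uniform(4, 12, len(times)))
        out, flags = telemetry.truncate_post_mortem(det)
        assert flags["F1"] is None
        assert len(out) == len(det)

    def test_all_constant_flagged_from_start(self):
        times = pd.date_range("2012-06-01", periods=5 * 24, freq="1h", tz="UTC")
        det = _det_frame(times, np.full(len(times), 9.0))
        out, flags = telemetry.truncate_post_mortem(det)
        assert flags["F1"] == times[0]
        assert len(out) <= 1


class TestCoa:
    def test_single_receiver_position(self):
        det = _det_frame(["2012-06-01 10:00", "2012-06-01 10:10"], [5.0, 7.0])
        coa = telemetry.compute_coa(det)
        assert len(coa) == 1
        assert coa.loc[0, "lon"] == 8.93 and coa.loc[0, "depth_m"] == 6.0

    def test_weighted_mean_three_to_one(self, detections_two_receivers):
        coa = telemetry.compute_coa(detections_two_receivers)
        assert len(coa) == 1
        assert coa.loc[0, "lon"] == pytest.approx(0.75 * 8.90 + 0.25 * 8.94)
        assert coa.loc[0, "lat"] == pytest.approx(0.75 * 58.60 + 0.25 * 58.64)

    def test_detection_conservation(self):
        rng = np.random.default_rng(4)
        times = pd.date_range("2012-06-01", periods=100, freq="7min", tz="UTC")
        det = _det_frame(times, rng.uniform(3, 9, 100))
        coa = telemetry.compute_coa(det)
        assert coa["n_detections"].sum() == 100

    def test_bins_aligned_to_half_hour(self):
        det = _det_frame(["2012-06-01 10:17", "2012-06-01 10:44"], [5.0, 5.0])
        coa = telemetry.compute_coa(det)
        assert list(coa["bin_start"].dt.minute) == [0, 30]


class TestSolar:
    def test_june_noon_is_day(self):
        # local solar noon ~ 11:24 UTC at lon 8.93
        out = solar.classify_daynight(
            pd.DatetimeIndex(["2012-06-21 11:24"], tz="UTC"), 58.62, 8.93
        )
        assert out[0] == "day"

    def test_midnight_is_night(self):
        out = solar.classify_daynight(
            pd.DatetimeIndex(["2012-06-20 23:24"], tz="UTC"), 58.62, 8.93
        )
        assert out[0] == "night"

    def test_solstice_noon_elevation(self):
        # closed-form check: max elevation = 90 - lat + declination
        elev = solar.solar_elevation(
            pd.DatetimeIndex(["2012-06-20 11:24"], tz="UTC"), 58.62, 8.93
        )[0]
        assert elev == pytest.approx(90 - 58.62 + 23.44, abs=0.6)
        elev_winter = solar.solar_elevation(
            pd.DatetimeIndex(["2012-12-21 11:24"], tz="UTC"), 58.62, 8.93
        )[0]
        assert elev_winter == pytest.approx(90 - 58.62 - 23.44, abs=0.6)

    def test_equinox_day_length(self):
        # at equinox the sun is up ~12 h everywhere
        times = pd.date_range("2012-03-20", "2012-03-21", freq="1min", tz="UTC")[:-1]
        frac_day = (solar.classify_daynight(times, 58.62, 8.93) == "day").mean()
        assert frac_day == pytest.approx(0.5, abs=0.02)


class TestMonthlyDepthTraits:
    def _coa(self, times, depths):
        return pd.DataFrame(
            {
                "fish_id": "F1",
                "bin_start": pd.DatetimeIndex(times, tz="UTC"),
                "lon": 8.93,
                "lat": 58.62,
                "depth_m": depths,
                "n_detections": 1,
            }
        )

    def test_constant_depth_zero_dvm(self):
        times = pd.date_range("2012-06-01", periods=48 * 10, freq="30min", tz="UTC")
        dvm = telemetry.monthly_dvm(self._coa(times, np.full(len(times), 8.0)), 58.62, 8.93)
        assert dvm["dvm_m"].iloc[0] == 0.0

    def test_forced_day_night_contrast(self):
        times = pd.date_range("2012-06-01", periods=48 * 10, freq="30min", tz="UTC")
        dn = solar.classify_daynight(times, 58.62, 8.93)
        depths = np.where(dn == "day", 10.0, 4.0)
        dvm = telemetry.monthly_dvm(self._coa(times, depths), 58.62, 8.93)
        assert dvm["dvm_m"].iloc[0] == pytest.approx(6.0)

    def test_daytime_depth_day_weighted(self):
        # two days at 10 m and 20 m with unequal detection counts -> 15 m
        t1 = pd.date_range("2012-06-01 10:00", periods=20, freq="30min", tz="UTC")
        t2 = pd.date_range("2012-06-02 11:00", periods=4, freq="30min", tz="UTC")
        coa = self._coa(t1.append(t2), np.r_[np.full(20, 10.0), np.full(4, 20.0)])
        out = telemetry.monthly_mean_daytime_depth(coa, 58.62, 8.93)
        assert out["daytime_depth_m"].iloc[0] == pytest.approx(15.0)

    def test_constant_12m(self):
        times = pd.date_range("2012-06-01 09:00", periods=48, freq="30min", tz="UTC")
        out = telemetry.monthly_mean_daytime_depth(
            self._coa(times, np.full(48, 12.0)), 58.62, 8.93
        )
        assert out["daytime_depth_m"].iloc[0] == pytest.approx(12.0)


class TestHomeRange:
    def test_bivariate_normal_analytic_area(self):
        rng = np.random.default_rng(5)
        sigma = 100.0
        x, y = rng.normal(0, sigma, size=(2, 500))
        area = telemetry.kud_area_km2(x, y, prob=0.95)
        expected = np.pi * CHI2_95 * sigma**2 / 1e6  # 0.188 km2
        assert area == pytest.approx(expected, rel=0.15)

    def test_doubling_sigma_quadruples_area(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 100.0, size=(2, 800))
        a1 = telemetry.kud_area_km2(x, y)
        a2 = telemetry.kud_area_km2(2 * x, 2 * y)
        assert a2 / a1 == pytest.approx(4.0, abs=0.5)

    def test_probability_monotone(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 80.0, size=(2, 400))
        assert telemetry.kud_area_km2(x, y, prob=0.50) < telemetry.kud_area_km2(x, y, prob=0.95)

    def test_presence_threshold(self):
        # 19 local days present -> no home-range row (times kept clear of
        # the local-midnight boundary)
        rng = np.random.default_rng(8)
        times = pd.date_range("2012-06-01 06:00", periods=19 * 24, freq="30min", tz="UTC")
        coa = pd.DataFrame(
            {
                "fish_id": "F1",
                "bin_start": times,
                "lon": 8.93 + rng.normal(0, 0.003, len(times)),
                "lat": 58.62 + rng.normal(0, 0.002, len(times)),
                "depth_m": 5.0,
                "n_detections": 1,
            }
        )
        out = telemetry.monthly_home_range(coa, min_days=20)
        assert out.empty

    def test_degenerate_positions_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            telemetry.kud_area_km2(np.zeros(50), np.zeros(50))


@pytest.fixture(scope="module")
def cohort():
    cfg = synthdata.TelemSimConfig(
        n_fish=12, study_days=45, fraction_dying=0.4, fraction_dispersing=0.25, seed=17
    )
    det, truth = synthdata.simulate_detections(cfg)
    det_f = telemetry.filter_false_detections(det)
    receivers = det[["receiver_id", "lon", "lat"]].drop_duplicates("receiver_id")
    battery_end = pd.Timestamp(cfg.start_date, tz="UTC") + pd.Timedelta(days=cfg.study_days)
    fates = telemetry.classify_fate(det_f, receivers, battery_end)
    return truth, {f.fish_id: f for f in fates}


class TestFate:

    def test_every_fish_has_one_fate(self, cohort):
        truth, called = cohort
        assert set(called) == set(truth.true_fate)
        assert all(f.fate in ("alive", "dispersed", "dead") for f in called.values())

    def test_dead_fish_recovered(self, cohort):
        truth, called = cohort
        dead = [k for k, v in truth.true_fate.items() if v == "dead"]
        assert all(called[k].fate == "dead" for k in dead)
        for k in dead:
            assert called[k].days_survived == pytest.approx(truth.true_death_day[k], abs=2)

    def test_alive_fish_recovered(self, cohort):
        truth, called = cohort
        alive = [k for k, v in truth.true_fate.items() if v == "alive"]
        assert all(called[k].fate == "alive" for k in alive)

    def test_dispersers_mostly_recovered(self, cohort):
        truth, called = cohort
        disp = [k for k, v in truth.true_fate.items() if v == "dispersed"]
        frac = np.mean([called[k].fate == "dispersed" for k in disp])
        assert frac >= 0.65


class TestRelativeLongevity:
    def _fates(self, days, fates=None):
        fates = fates or ["dead"] * len(days)
        return [
            telemetry.FateRecord(f"F{i}", fa, pd.Timestamp("2012-01-01", tz="UTC"), d)
            for i, (d, fa) in enumerate(zip(days, fates))
        ]

    def test_equal_days_all_one(self):
        out = telemetry.relative_longevity(self._fates([200.0, 200.0, 200.0]))
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_forced_values(self):
        out = telemetry.relative_longevity(self._fates([100.0, 300.0]))
        assert sorted(out.values()) == pytest.approx([0.5, 1.5])

    def test_mean_is_one_and_dispersed_excluded(self):
        fates = self._fates([100, 200, 300, 999], ["dead", "alive", "dead", "dispersed"])
        out = telemetry.relative_longevity(fates)
        assert "F3" not in out
        assert np.mean(list(out.values())) == pytest.approx(1.0)

    def test_all_dispersed_rejected(self):
        with pytest.raises(ValueError):
            telemetry.relative_longevity(self._fates([100.0], ["dispersed"]))
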