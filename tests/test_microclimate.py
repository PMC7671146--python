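"""Synthetic microclimate: rock fields, temperature series, summaries,
logger CSV I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from hotrocks import microclimate as mc
from hotrocks.tides import TideModel


class TestRockField:
    def test_field_respects_printed_ranges_and_means(self, default_cfg):
        rocks = mc.generate_rock_field(12, 12, seed=1, config=default_cfg)
        assert len(rocks) == 24
        miz = [r for r in rocks if r.zone == "MIZ"]
        hiz = [r for r in rocks if r.zone == "HIZ"]
        assert len(miz) == len(hiz) == 12
        for r in miz:
            assert -0.32 <= r.elevation <= 0.23
        for r in hiz:
            assert 0.31 <= r.elevation <= 1.10
        for r in rocks:
            assert 568 <= r.surface_area <= 2671
            assert 5162 <= r.volume <= 50472
        assert -0.1 <= np.mean([r.elevation for r in miz]) <= 0.1
        assert 0.65 <= np.mean([r.elevation for r in hiz]) <= 0.95

    def test_single_miz_rock(self):
        rocks = mc.generate_rock_field(1, 0, seed=7)
        assert len(rocks) == 1 and rocks[0].zone == "MIZ"
        assert -0.32 <= rocks[0].elevation <= 0.23

    def test_seeded_determinism(self):
        assert mc.generate_rock_field(12, 12, seed=1) == mc.generate_rock_field(
            12, 12, seed=1
        )

    @pytest.mark.parametrize("n_miz,n_hiz", [(0, 0), (-1, 5)])
    def test_invalid_counts_rejected(self, n_miz, n_hiz):
        with pytest.raises(ValueError):
            mc.generate_rock_field(n_miz, n_hiz, seed=1)

    def test_zone_consistent_with_elevation(self, rock_field):
        for r in rock_field:
            assert (r.elevation < 0.31) == (r.zone == "MIZ")


class TestTemperatureSeries:
    def test_record_grid_and_bounds(self, year_records, rock_field):
        per_rock = year_records.groupby("rock_id")["timestamp"]
        for _, ts in per_rock:
            diffs = ts.diff().dropna()
            assert (diffs == pd.Timedelta(minutes=30)).all()
        assert year_records["temperature"].between(-5, 45).all()
        assert len(year_records) == len(rock_field) * 366 * 48  # leap year

    def test_immersed_rocks_share_water_temperature_exactly(self, year_records):
        immersed = year_records[~year_records["emersed"]]
        spread = immersed.groupby("timestamp")["temperature"].agg(lambda v: v.max() - v.min())
        assert (spread == 0.0).all()

    def test_seeded_bit_reproducibility(self, rock_field, calibration, tide_model):
        kwargs = dict(
            rocks=rock_field[:3], start="2016-05-01", end="2016-05-08",
            calib=calibration, tide=tide_model, seed=9,
        )
        a = mc.simulate_temperature_series(**kwargs)
        b = mc.simulate_temperature_series(**kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rock_list_rejected(self, calibration, tide_model):
        with pytest.raises(ValueError, match="empty"):
            mc.simulate_temperature_series(
                [], "2016-01-01", "2016-02-01", calibration, tide_model, seed=0
            )

    def test_start_must_precede_end(self, rock_field, calibration, tide_model):
        with pytest.raises(ValueError, match="precede"):
            mc.simulate_temperature_series(
                rock_field, "2016-02-01", "2016-01-01", calibration, tide_model, seed=0
            )

    def test_mean_daily_maximum_rank_correlates_with_elevation(
        self, daily_summaries, rock_field
    ):
        per_rock = daily_summaries.groupby("rock_id")["t_max"].mean()
        elev = pd.Series({r.rock_id: r.elevation for r in rock_field})
        rho = spearmanr(elev[per_rock.index], per_rock)[0]
        assert rho > 0

    def test_among_rock_spread_of_maxima_higher_in_hiz(self, daily_summaries):
        per_rock = daily_summaries.groupby(["zone", "rock_id"])["t_max"].mean()
        assert per_rock["HIZ"].std() > 2 * per_rock["MIZ"].std()

    def test_exclusion_window_removes_records(self, rock_field, tide_model, default_cfg):
        block = dict(default_cfg["microclimate"])
        block = {**block, "exclusion_windows": [["2016-02-01", "2016-04-03"]]}
        calib = mc.MicroclimateCalibration.from_config(block)
        rec = mc.simulate_temperature_series(
            rock_field[:2], "2016-01-01", "2016-06-01", calib, tide_model, seed=3
        )
        assert not rec["timestamp"].between("2016-02-01", "2016-04-03").any()
        assert rec["timestamp"].between("2016-01-01", "2016-01-31").any()


class TestDailySummary:
    def test_single_day_reduction(self):
        rec = pd.DataFrame(
            {
                "rock_id": "r1",
                "timestamp": pd.to_datetime(
                    ["2016-07-01 08:00", "2016-07-01 12:00", "2016-07-01 16:00"]
                ),
                "temperature": [10.0, 12.0, 14.0],
                "emersed": False,
            }
        )
        s = mc.summarize_daily(rec)
        assert len(s) == 1
        row = s.iloc[0]
        assert (row.t_max, row.t_min, row.t_mean, row.t_range, row.n_records) == (
            14.0, 10.0, 12.0, 4.0, 3,
        )

    def test_constant_day_has_zero_range(self):
        rec = pd.DataFrame(
            {
                "rock_id": "r1",
                "timestamp": pd.date_range("2016-07-01", periods=48, freq="30min"),
                "temperature": 13.0,
                "emersed": False,
            }
        )
        assert mc.summarize_daily(rec)["t_range"].iloc[0] == 0.0

    def test_empty_input_gives_empty_output(self):
        assert len(mc.summarize_daily(pd.DataFrame(columns=["rock_id", "timestamp", "temperature"]))) == 0

    def test_min_le_mean_le_max_all_rock_days(self, daily_summaries):
        assert (daily_summaries["t_min"] <= daily_summaries["t_mean"] + 1e-12).all()
        assert (daily_summaries["t_mean"] <= daily_summaries["t_max"] + 1e-12).all()
        assert (daily_summaries["t_range"] >= 0).all()

    def test_daily_warmest_coolest_gap_larger_in_hiz(self, daily_summaries):
        def daily_gap(zone):
            sub = daily_summaries[daily_summaries["zone"] == zone]
            per_day = sub.groupby("date")["t_max"].agg(lambda v: v.max() - v.min())
            return per_day.mean()

        assert daily_gap("HIZ") > daily_gap("MIZ")


class TestSeasonalSummary:
    def test_single_season_input_omits_other_season(self):
        s = pd.DataFrame(
            {
                "rock_id": "r1",
                "zone": "HIZ",
                "date": pd.to_datetime(["2016-07-01", "2016-07-02"]),
                "t_max": [20.0, 21.0],
            }
        )
        table = mc.seasonal_summary(s)
        assert set(table["season"]) == {mc.SPRING_SUMMER}

    def test_season_boundaries(self):
        assert mc.season_of("2016-03-20") == mc.SPRING_SUMMER
        assert mc.season_of("2016-09-21") == mc.SPRING_SUMMER
        assert mc.season_of("2016-03-19") == mc.FALL_WINTER
        assert mc.season_of("2016-09-22") == mc.FALL_WINTER

    def test_spring_summer_maxima_warmer_and_contrast_stronger_in_hiz(
        self, daily_summaries
    ):
        table = mc.seasonal_summary(daily_summaries).set_index(["zone", "season"])
        diff = {
            z: table.loc[(z, mc.SPRING_SUMMER), "mean_t_max"]
            - table.loc[(z, mc.FALL_WINTER), "mean_t_max"]
            for z in ("MIZ", "HIZ")
        }
        assert diff["HIZ"] > 0 and diff["MIZ"] > 0
        assert diff["HIZ"] > diff["MIZ"]


class TestLoggerCsv:
    def test_round_trip_identity(self, tmp_path, year_records):
        path = tmp_path / "records.csv"
        subset = year_records.iloc[:100][["rock_id", "timestamp", "temperature"]]
        mc.write_logger_csv(year_records.iloc[:100], path)
        back, report = mc.read_logger_csv(path)
        assert report.n_skipped == 0
        pd.testing.assert_frame_equal(back, subset.reset_index(drop=True))

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("rock_id,timestamp,temperature_C\n")
        records, report = mc.read_logger_csv(path)
        assert len(records) == 0 and report.n_skipped == 0

    def test_na_temperature_skipped_and_counted_with_line_number(self, tmp_path):
        path = tmp_path / "na.csv"
        path.write_text(
            "rock_id,timestamp,temperature_C\n"
            "r1,2016-01-01T00:00:00,12.5\n"
            "r1,2016-01-01T00:30:00,NA\n"
            "r1,not-a-time,13.0\n"
        )
        records, report = mc.read_logger_csv(path)
        assert len(records) == 1
        assert report.skipped == [(3, "bad temperature"), (4, "bad timestamp")]

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("rock_id,when,temp\nr1,2016-01-01,12\n")
        with pytest.raises(mc.LoggerFormatError, match="timestamp"):
            mc.read_logger_csv(path)
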