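"""Field stream synchronization, torpor flags, summaries and regressions."""

import numpy as np
import pandas as pd
import pytest

from cardiomet import calibration as cal
from cardiomet import field as fld
from cardiomet import synthetic as syn


@pytest.fixture(scope="module")
def torpor_dataset():
    return syn.simulate_field_dataset(
        duration_h=36.0, torpor_schedule=((14.0, 18.0),), seed=1
    )


@pytest.fixture(scope="module")
def torpor_records(torpor_dataset):
    fd = torpor_dataset
    return fld.sync_streams(fd.hr, fd.tb, fd.ta)


class TestSyncStreams:
    def test_constant_streams_give_constant_records(self):
        ts = pd.date_range("2017-03-01", periods=120, freq="60s")
        hr = pd.DataFrame({"timestamp": ts, "individual": "a", "bpm": 150.0})
        tb = pd.DataFrame({"timestamp": ts[1:], "individual": "a", "t_b": 33.0})
        ta = pd.DataFrame({"timestamp": ts[::15], "t_a": 25.0})
        rec = fld.sync_streams(hr, tb, ta)
        assert np.allclose(rec["f_h"].dropna(), 150.0)
        assert np.allclose(rec["t_b"], 33.0)
        assert np.allclose(rec["t_diff"], 8.0)

    def test_ta_matches_ground_truth_at_gridpoints(self, torpor_dataset, torpor_records):
        fd = torpor_dataset
        grid = torpor_records.merge(fd.ta, on="timestamp", suffixes=("", "_truth"))
        assert len(grid) > 0
        np.testing.assert_allclose(grid["t_a"], grid["t_a_truth"])

    def test_sparse_tb_cadence_no_fabricated_records(self):
        fd = syn.simulate_field_dataset(
            duration_h=6.0, tb_cadence_s=600.0, fh_cadence_s=600.0, seed=4
        )
        rec = fld.sync_streams(fd.hr, fd.tb, fd.ta)
        assert len(rec) == len(fd.tb)  # one record per T_b observation

    def test_zero_overlap_rejected(self):
        hr = pd.DataFrame(
            {"timestamp": pd.date_range("2017-01-01", periods=10, freq="60s"),
             "individual": "a", "bpm": 100.0}
        )
        tb = pd.DataFrame(
            {"timestamp": pd.date_range("2018-01-01", periods=10, freq="60s"),
             "individual": "a", "t_b": 33.0}
        )
        ta = pd.DataFrame({"timestamp": hr["timestamp"], "t_a": 25.0})
        with pytest.raises(ValueError):
            fld.sync_streams(hr, tb, ta)

    def test_body_below_ambient_retained_flagged(self):
        ts = pd.date_range("2017-03-01", periods=30, freq="60s")
        hr = pd.DataFrame({"timestamp": ts, "individual": "a", "bpm": 80.0})
        tb = pd.DataFrame({"timestamp": ts, "individual": "a", "t_b": 24.0})
        ta = pd.DataFrame({"timestamp": ts[::15], "t_a": 25.0})
        rec = fld.sync_streams(hr, tb, ta)
        assert rec["below_ambient"].all()
        assert len(rec) == 30


class TestLowStateClassification:
    def test_bottom_decile_sort_oracle(self):
        vals = np.arange(10.0, 1001.0, 10.0)  # 100 values
        rec = pd.DataFrame(
            {
                "timestamp": pd.date_range("2017-03-01", periods=100, freq="600s"),
                "individual": "a",
                "f_h": vals,
            }
        )
        out, thr, hours = fld.classify_low_state(rec)
        assert thr == pytest.approx(np.quantile(vals, 0.10))
        flagged = set(out.loc[out["low_state"], "f_h"])
        brute = set(np.sort(vals)[: np.sum(vals <= np.quantile(vals, 0.10))])
        assert flagged == brute

    def test_all_equal_all_flagged(self):
        rec = pd.DataFrame(
            {
                "timestamp": pd.date_range("2017-03-01", periods=20, freq="60s"),
                "individual": "a",
                "f_h": 100.0,
            }
        )
        out, _, _ = fld.classify_low_state(rec)
        assert out["low_state"].all()

    def test_torpor_bout_hours_flagged(self, torpor_dataset, torpor_records):
        # the pooled decile threshold falls between the torpid and active
        # heart-rate distributions, so every flagged hour is a bout hour
        out, thr, hours = fld.classify_low_state(torpor_records)
        start, end = torpor_dataset.torpor_intervals[0]
        in_bout = (out["timestamp"] >= start) & (out["timestamp"] < end)
        bout_hours = set(pd.DatetimeIndex(out.loc[in_bout, "timestamp"]).hour)
        assert bout_hours <= set(hours)
        assert thr < 100.0  # below the active floor

    def test_record_level_sensitivity_specificity(self):
        # a quantile classifier flags exactly its quantile's share of
        # records, so the bout here occupies less than a decile of the
        # record (3 h of 36 h) and both error rates must stay under 10%
        fd = syn.simulate_field_dataset(
            duration_h=36.0, torpor_schedule=((14.0, 17.0),), seed=8
        )
        out, thr, _ = fld.classify_low_state(fld.sync_streams(fd.hr, fd.tb, fd.ta))
        start, end = fd.torpor_intervals[0]
        has_fh = out["f_h"].notna()
        truth = ((out["timestamp"] >= start) & (out["timestamp"] < end))[has_fh].to_numpy()
        flag = out.loc[has_fh, "low_state"].to_numpy()
        assert flag[truth].mean() >= 0.9  # sensitivity
        assert (~flag[~truth]).mean() >= 0.9  # specificity

    def test_insufficient_data_rejected(self):
        rec = pd.DataFrame(
            {
                "timestamp": pd.date_range("2017-03-01", periods=5, freq="60s"),
                "individual": "a",
                "f_h": 100.0,
            }
        )
        with pytest.raises(ValueError):
            fld.classify_low_state(rec)


class TestHourlySummary:
    def test_single_record_single_hour(self):
        rec = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp("2017-03-01 13:05")],
                "individual": "a",
                "f_h": [120.0],
                "t_b": [33.0],
            }
        )
        summary = fld.hourly_summary(rec)
        assert summary.loc[13, "f_h_n"] == 1
        assert summary.loc[13, "f_h_mean"] == 120.0
        empty = summary.drop(index=13)
        assert (empty["f_h_n"] == 0).all()
        assert empty["f_h_mean"].isna().all()

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(0)
        ts = pd.Timestamp("2017-03-01") + pd.to_timedelta(
            np.sort(rng.uniform(0, 72 * 3600, 1000)), unit="s"
        )
        rec = pd.DataFrame(
            {
                "timestamp": ts,
                "individual": "a",
                "f_h": rng.uniform(50, 900, 1000),
                "t_b": rng.uniform(25, 37, 1000),
            }
        )
        summary = fld.hourly_summary(rec)
        hours = pd.DatetimeIndex(rec["timestamp"]).hour
        for h in range(24):
            sel = rec[hours == h]
            assert summary.loc[h, "f_h_n"] == len(sel)
            if len(sel):
                assert summary.loc[h, "f_h_mean"] == pytest.approx(sel["f_h"].mean())
                assert summary.loc[h, "t_b_mean"] == pytest.approx(sel["t_b"].mean())
            if len(sel) > 1:
                assert summary.loc[h, "f_h_sd"] == pytest.approx(sel["f_h"].std(ddof=1))


class TestScotophase:
    @pytest.mark.parametrize(
        "when,expected",
        [
            ("2017-03-01 00:00", True),
            ("2017-03-01 12:00", False),
            ("2017-03-01 18:15", True),  # closed at dusk
            ("2017-03-01 06:15", False),  # open at dawn
            ("2017-03-01 06:14:59", True),
        ],
    )
    def test_defaults(self, when, expected):
        assert fld.scotophase_annotation([pd.Timestamp(when)])[0] == expected

    def test_equal_bounds_rejected(self):
        with pytest.raises(ValueError):
            fld.scotophase_annotation([pd.Timestamp("2017-03-01")], "12:00", "12:00")


class TestFieldRegressions:
    @staticmethod
    def _synthetic_records(seed, n_ind=6, n_obs=150):
        """Field-like table generated from the published linear relations."""
        rng = np.random.default_rng(seed)
        ind = np.repeat([f"bat{i}" for i in range(n_ind)], n_obs)
        t_a = rng.uniform(22.0, 29.0, ind.size)
        t_b = (
            16.0 + 0.481 * t_a
            + rng.normal(0, 1.0, n_ind)[np.repeat(np.arange(n_ind), n_obs)]
            + rng.normal(0, 1.5, ind.size)
        )
        f_h = (
            syn.FH_TB_INTERCEPT + syn.FH_TB_SLOPE * t_b
            + rng.normal(0, 18.35, n_ind)[np.repeat(np.arange(n_ind), n_obs)]
            + rng.normal(0, 38.93, ind.size)
        )
        ts = pd.Timestamp("2017-03-01") + pd.to_timedelta(np.arange(ind.size) * 60, unit="s")
        return pd.DataFrame(
            {"timestamp": ts, "individual": ind, "f_h": f_h,
             "t_b": t_b, "t_a": t_a, "t_diff": t_b - t_a}
        )

    def test_published_slopes_recovered(self):
        """Mean recovered slopes match the generating field relations."""
        tb_ta, fh_tb = [], []
        for seed in range(30):
            table = fld.field_regressions(self._synthetic_records(seed)).set_index("model")
            tb_ta.append(table.loc["t_b ~ t_a", "slope"])
            fh_tb.append(table.loc["f_h ~ t_b", "slope"])
            assert (table["p"] < 0.01).iloc[:2].all()
        assert np.mean(tb_ta) == pytest.approx(0.481, rel=0.15)
        assert np.mean(fh_tb) == pytest.approx(syn.FH_TB_SLOPE, rel=0.10)

    def test_zero_slope_interval_coverage(self):
        """95% Wald intervals cover zero at roughly the nominal rate."""
        covered = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed + 5000)
            ind = np.repeat([f"b{i}" for i in range(5)], 60)
            x = rng.uniform(22, 29, ind.size)
            y = 30.0 + rng.normal(0, 1.0, 5)[np.repeat(np.arange(5), 60)] + rng.normal(0, 1.5, ind.size)
            df = pd.DataFrame({"individual": ind, "t_a": x, "t_b": y})
            fit = cal.fit_random_intercept(df, ("t_a",), response="t_b")
            se = fit.result.bse_fe[1]
            covered += abs(fit.beta["t_a"]) <= 1.96 * se
        assert 0.88 <= covered / n_rep <= 1.0

    def test_uses_calibration_fitting_path(self, torpor_records, monkeypatch):
        """No second fitting machinery: the regressions call the calibration module."""
        calls = []
        orig = cal.fit_random_intercept

        def spy(*args, **kwargs):
            calls.append(1)
            return orig(*args, **kwargs)

        rec = pd.concat(
            [
                torpor_records,
                torpor_records.assign(individual="bat_b", f_h=torpor_records["f_h"] * 1.05),
            ],
            ignore_index=True,
        )
        monkeypatch.setattr(cal, "fit_random_intercept", spy)
        fld.field_regressions(rec)
        assert len(calls) == 6  # three models plus three nulls


class TestExpenditure:
    def test_constant_full_day_total(self):
        ts = pd.date_range("2017-03-01", periods=1440, freq="60s")
        rec = pd.DataFrame(
            {"timestamp": ts, "individual": "a", "f_h": 147.0}
        )
        per_rec, totals = fld.predict_field_expenditure(rec)
        expected_rate = 0.00106 * 147.0 + 0.0527  # kJ/day
        assert np.allclose(per_rec["expenditure_rate"], expected_rate)
        assert totals.loc[0, "total_kj"] == pytest.approx(expected_rate, rel=0.01)
        assert not totals.loc[0, "unreliable"]

    def test_zero_rate_gives_intercept(self):
        ts = pd.date_range("2017-03-01", periods=20, freq="60s")
        rec = pd.DataFrame({"timestamp": ts, "individual": "a", "f_h": 0.0})
        per_rec, _ = fld.predict_field_expenditure(rec)
        assert np.allclose(per_rec["expenditure_rate"], 0.0527)

    def test_total_scales_with_coverage_no_imputation(self):
        full = pd.date_range("2017-03-01", periods=1440, freq="60s")
        part = full[:600]  # 10 of 24 h covered
        rec_full = pd.DataFrame({"timestamp": full, "individual": "a", "f_h": 147.0})
        rec_part = pd.DataFrame({"timestamp": part, "individual": "a", "f_h": 147.0})
        _, t_full = fld.predict_field_expenditure(rec_full)
        _, t_part = fld.predict_field_expenditure(rec_part)
        assert t_part.loc[0, "total_kj"] == pytest.approx(
            t_full.loc[0, "total_kj"] * 600 / 1440, rel=0.01
        )
        assert t_part.loc[0, "unreliable"]  # > 50% of the day uncovered
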