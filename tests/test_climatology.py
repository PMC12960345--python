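import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from histbioclim import climatology
from histbioclim.climatology import (
    SEASONS, anomalies, build_report, contemporary_normals,
    envelope_exceedance, monthly_stats, percent_days_below, seasonal_stats,
)


def _dates(year, month, days):
    return {dt.date(year, month, d).isoformat(): v for d, v in days}


class TestMonthlyStats:
    def test_constant_month(self):
        values = _dates(1767, 9, [(d, 5.0) for d in range(1, 31)])
        df = monthly_stats(values, "t")
        assert len(df) == 1
        row = df.iloc[0]
        assert (row["mean"], row["min"], row["max"]) == (5.0, 5.0, 5.0)
        assert row["n_obs"] == 30 and not row["partial"]
        assert not row["low_coverage"]

    def test_partial_month_flagged_not_dropped(self):
        # 22 of 31 July days observed, like an expedition's last month
        values = _dates(1768, 7, [(d, 12.5) for d in range(1, 23)])
        df = monthly_stats(values, "t")
        assert len(df) == 1
        assert df.iloc[0]["partial"]
        assert not df.iloc[0]["low_coverage"]  # 0.71 is above the 0.7 floor
        assert df.iloc[0]["coverage"] == pytest.approx(22 / 31)

    def test_empty_month_emits_no_row(self):
        assert monthly_stats({}, "t").empty

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = list(rng.normal(size=28))
        days = list(range(1, 29))
        a = monthly_stats(_dates(1790, 2, list(zip(days, vals))), "t")
        perm = rng.permutation(28)
        b = monthly_stats(_dates(1790, 2, [(days[i], vals[i]) for i in perm]),
                          "t")
        pd.testing.assert_frame_equal(a, b)


class TestSeasonalStats:
    def test_equal_month_weighting(self):
        monthly = pd.DataFrame([
            {"year": 1790, "month": m, "variable": "t", "mean": v,
             "min": v, "max": v, "n_obs": 30, "coverage": 1.0,
             "partial": False}
            for m, v in [(3, -4.4), (4, -13.1), (5, -8.5)]
        ])
        df = seasonal_stats(monthly)
        row = df[df.season == "Mar-May"]
        assert float(row["mean"].iloc[0]) == pytest.approx(
            (-4.4 - 13.1 - 8.5) / 3)

    def test_missing_month_omits_season(self):
        monthly = pd.DataFrame([
            {"year": 1790, "month": m, "variable": "t", "mean": 1.0,
             "min": 1.0, "max": 1.0, "n_obs": 30, "coverage": 1.0,
             "partial": False}
            for m in (1, 3, 4, 5, 6)  # February missing
        ])
        df = seasonal_stats(monthly)
        assert df[df.season == "Jan-Jun"].empty
        assert not df[df.season == "Mar-May"].empty

    def test_winter_assigned_to_january_year(self):
        # Dec 1790 + Jan/Feb 1791 -> winter 1791
        rows = [(1790, 12, -8.0), (1791, 1, -10.0), (1791, 2, -12.0)]
        monthly = pd.DataFrame([
            {"year": y, "month": m, "variable": "t", "mean": v, "min": v,
             "max": v, "n_obs": 30, "coverage": 1.0, "partial": False}
            for y, m, v in rows
        ])
        df = seasonal_stats(monthly)
        winter = df[df.season == "Dec-Feb"]
        assert list(winter["year"]) == [1791]
        assert float(winter["mean"].iloc[0]) == pytest.approx(-10.0)


class TestContemporaryNormals:
    def test_constant_series_zero_sd(self):
        values = {}
        for year in (2000, 2001, 2002):
            for doy in range(0, 365, 1):
                d = dt.date(year, 1, 1) + dt.timedelta(days=doy)
                values[d.isoformat()] = 3.0
        normals = contemporary_normals(values, window=15)
        assert np.allclose(normals.monthly["sd"], 0.0)
        assert np.allclose(normals.daily["sd"].dropna(), 0.0)
        assert np.allclose(normals.daily["mean"].dropna(), 3.0)
        assert len(normals.daily) == 366

    def test_single_year_rejected(self):
        values = _dates(2000, 1, [(d, 1.0) for d in range(1, 32)])
        with pytest.raises(ValueError, match="2 distinct years"):
            contemporary_normals(values)

    def test_leap_day_has_a_populated_slot(self):
        values = {}
        for year in (1999, 2000, 2001, 2002):
            d = dt.date(year, 1, 1)
            while d.year == year:
                values[d.isoformat()] = float(d.month)
                d += dt.timedelta(days=1)
        normals = contemporary_normals(values, window=15)
        feb29 = normals.daily[normals.daily.doy == 60]
        assert np.isfinite(feb29["mean"].iloc[0])
        assert feb29["n_obs"].iloc[0] > 0

    def test_parameter_recovery_on_gaussian_series(self):
        rng = np.random.default_rng(42)
        n_years, sd = 30, 2.0
        values = {}
        for year in range(1991, 1991 + n_years):
            d = dt.date(year, 1, 1)
            while d.year == year:
                values[d.isoformat()] = float(rng.normal(1.5, sd))
                d += dt.timedelta(days=1)
        normals = contemporary_normals(values, window=15)
        se = sd / np.sqrt(30 * n_years)  # per-month sampling error
        assert np.all(np.abs(normals.monthly["mean"] - 1.5) < 3 * se)
        assert normals.monthly["sd"].mean() == pytest.approx(sd, rel=0.05)


class TestAnomalies:
    def test_january_worked_example(self):
        """Historical January mean -18.2 against normal -7.6 -> -10.6."""
        hist = pd.DataFrame([{"year": 1791, "month": 1, "variable": "t",
                              "mean": -18.2, "min": -27.4, "max": -5.0,
                              "n_obs": 31, "coverage": 1.0, "partial": False}])
        normals = climatology.NormalsTable(
            monthly=pd.DataFrame([{"month": 1, "mean": -7.6, "sd": 3.0,
                                   "min": -25.0, "max": 5.0, "n_obs": 900}]),
            daily=pd.DataFrame({"doy": [1], "mean": [np.nan], "sd": [np.nan],
                                "n_obs": [0]}))
        df = anomalies(hist, normals)
        assert float(df["anomaly"].iloc[0]) == pytest.approx(-10.6, abs=1e-12)

    def test_self_comparison_is_zero(self):
        values = {}
        rng = np.random.default_rng(3)
        for year in (2000, 2001, 2002):
            d = dt.date(year, 1, 1)
            while d.year == year:
                values[d.isoformat()] = float(rng.normal())
                d += dt.timedelta(days=1)
        monthly = monthly_stats(values, "t")
        pooled = monthly.groupby("month", as_index=False).agg(
            year=("year", "first"), variable=("variable", "first"),
            mean=("mean", "mean"))
        # anomaly of the pooled monthly means against their own normals
        normals = contemporary_normals(values)
        df = anomalies(pooled.assign(year=2000), normals)
        # monthly normal pools observations; equal-length months agree exactly,
        # small deviations only from unequal year lengths
        assert np.all(np.abs(df["anomaly"]) < 0.05)

    def test_month_absent_from_normals_omitted(self):
        hist = pd.DataFrame([{"year": 1791, "month": 7, "variable": "t",
                              "mean": 12.5, "min": 5.0, "max": 17.8,
                              "n_obs": 22, "coverage": 0.7, "partial": True}])
        normals = climatology.NormalsTable(
            monthly=pd.DataFrame([{"month": 1, "mean": -7.6, "sd": 3.0,
                                   "min": -25.0, "max": 5.0, "n_obs": 900}]),
            daily=pd.DataFrame({"doy": [1], "mean": [np.nan], "sd": [np.nan],
                                "n_obs": [0]}))
        assert anomalies(hist, normals).empty


def _gaussian_series(seed, n_years=30, mean=0.0, sd=1.0, start=1991):
    rng = np.random.default_rng(seed)
    values = {}
    for year in range(start, start + n_years):
        d = dt.date(year, 1, 1)
        while d.year == year:
            values[d.isoformat()] = float(rng.normal(mean, sd))
            d += dt.timedelta(days=1)
    return values


class TestEnvelopeExceedance:
    def test_boundary_is_strict(self):
        normals = climatology.NormalsTable(
            monthly=pd.DataFrame(), window=1,
            daily=pd.DataFrame({"doy": np.arange(1, 367),
                                "mean": 0.0, "sd": 1.0,
                                "n_obs": 30}))
        at_edge = {"2000-01-05": 2.0}       # exactly mean + 2 SD
        beyond = {"2000-01-05": 2.0001}
        assert envelope_exceedance(at_edge, normals, k=2).iloc[-1]["n_exceed"] == 0
        assert envelope_exceedance(beyond, normals, k=2).iloc[-1]["n_exceed"] == 1

    def test_k_zero_flags_every_unequal_value(self):
        normals = climatology.NormalsTable(
            monthly=pd.DataFrame(), window=1,
            daily=pd.DataFrame({"doy": np.arange(1, 367),
                                "mean": 0.0, "sd": 1.0, "n_obs": 30}))
        values = {"2000-01-05": 0.0, "2000-01-06": 0.3, "2000-01-07": -0.2}
        out = envelope_exceedance(values, normals, k=0)
        assert int(out.iloc[-1]["n_exceed"]) == 2

    def test_gaussian_self_exceedance_near_theory(self):
        """|x - mean| > 2 SD on ~2(1-Phi(2)) = 4.55% of days."""
        values = _gaussian_series(7)
        normals = contemporary_normals(values, window=15)
        out = envelope_exceedance(values, normals, k=2.0)
        frac = float(out.loc[out.month == 0, "fraction"].iloc[0])
        assert frac == pytest.approx(2 * (1 - norm.cdf(2)), abs=0.01)


class TestPercentDaysBelow:
    def test_strict_inequality(self):
        values = {"2000-01-01": -1.0, "2000-01-02": 0.0, "2000-01-03": 1.0}
        assert percent_days_below(values, 0.0) == pytest.approx(100 / 3)

    def test_all_below(self):
        values = {"2000-01-01": -1.0, "2000-01-02": -2.0}
        assert percent_days_below(values, 0.0) == 100.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            percent_days_below({"2000-01-01": np.nan}, 0.0)

    def test_matches_analytic_cdf_on_gaussian(self):
        values = _gaussian_series(11, mean=1.0, sd=2.0)
        expected = 100 * norm.cdf((0 - 1.0) / 2.0)
        assert percent_days_below(values, 0.0) == pytest.approx(expected,
                                                                abs=1.0)


class TestBuildReport:
    def test_reruns_are_byte_identical_with_provenance(self, tmp_path):
        frames = {
            "monthly": pd.DataFrame({"month": [1, 2], "mean": [-7.6, -8.2]}),
            "flags": pd.DataFrame({"x": [1]}),
        }
        rep1 = build_report(frames, tmp_path / "a", {"seed": 1})
        rep2 = build_report(frames, tmp_path / "b", {"seed": 1})
        assert rep1.provenance["content_hash"] == rep2.provenance["content_hash"]
        for name in ("monthly.csv", "flags.csv", "report.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
        first = (tmp_path / "a" / "monthly.csv").read_text().splitlines()[0]
        assert first.startswith("# provenance:")

    def test_empty_report_is_valid(self, tmp_path):
        rep = build_report({}, tmp_path / "empty")
        assert (tmp_path / "empty" / "report.json").exists()
        assert rep.fragments == {}
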