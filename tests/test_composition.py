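"""Daily interpolation, annual compositions and the cell-volume filter."""

import numpy as np
import pandas as pd
import pytest

import traitsort as ts
from traitsort.composition import daily_series

from conftest import make_observations


def _grid(start, end):
    return pd.date_range(start, end, freq="D")


class TestDailySeries:
    def test_single_observation_extends_constant(self):
        grid = _grid("1980-01-01", "1980-12-31")
        out = daily_series(["1980-06-15"], [7.5], grid)
        assert np.all(out == 7.5)

    def test_linear_midpoint(self):
        grid = _grid("1980-01-01", "1980-01-11")
        out = daily_series(["1980-01-01", "1980-01-11"], [0.0, 10.0], grid)
        assert out[5] == 5.0  # day 6 of the ramp

    def test_constant_extension_beyond_samples(self):
        grid = _grid("1980-01-01", "1980-03-01")
        out = daily_series(["1980-02-01", "1980-02-10"], [3.0, 6.0], grid)
        assert np.all(out[:31] == 3.0)
        assert np.all(out[40:] == 6.0)

    def test_annual_mean_matches_bruteforce_day_sum(self):
        """Mean of the interpolated ramp equals an explicit day-by-day sum."""
        dates = ["1981-01-01", "1981-05-11", "1981-12-31"]
        values = [2.0, 12.0, 4.0]
        grid = _grid("1981-01-01", "1981-12-31")
        out = daily_series(dates, values, grid)
        # independent brute force: walk every day, interpolate by hand
        day_nums = (pd.DatetimeIndex(dates) - pd.Timestamp("1981-01-01")).days.to_numpy()
        total = 0.0
        for d in range(365):
            j = np.searchsorted(day_nums, d, side="right")
            if j == 0:
                v = values[0]
            elif j == len(day_nums):
                v = values[-1]
            else:
                d0, d1 = day_nums[j - 1], day_nums[j]
                f = (d - d0) / (d1 - d0)
                v = values[j - 1] * (1 - f) + values[j] * f
            total += v
        assert np.mean(out) == pytest.approx(total / 365, abs=1e-12)

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="empty"):
            daily_series([], [], _grid("1980-01-01", "1980-01-02"))


class TestFilterSmallCells:
    def test_strict_threshold_boundary(self):
        obs = make_observations(
            [("1980-06-01", "big", 1.0), ("1980-06-01", "edge", 1.0), ("1980-06-01", "small", 1.0)],
            [("big", 120.0, "C1"), ("edge", 30.0, "C1"), ("small", 29.999, "C1")],
        )
        kept, report = ts.filter_small_cells(obs, threshold=30.0)
        assert "edge" in kept.taxa and "small" not in kept.taxa
        assert report.excluded_taxa == ("small",)

    def test_zero_threshold_excludes_nothing(self):
        obs = make_observations(
            [("1980-06-01", "a", 1.0)], [("a", 5.0, "C1")]
        )
        kept, report = ts.filter_small_cells(obs, threshold=0.0)
        assert kept == obs
        assert report.fraction_taxa_excluded == 0.0
        assert report.mean_biovolume_share == 0.0

    def test_generator_share_recovered(self, default_dataset, default_composition):
        """Small-cell taxa built to hold 1.8% of biovolume report that share."""
        _, report, _ = default_composition
        cfg = default_dataset.config
        assert report.fraction_taxa_excluded == pytest.approx(
            cfg.small_cell_fraction, abs=0.01
        )
        assert report.mean_biovolume_share == pytest.approx(
            cfg.small_cell_share, abs=0.005
        )


class TestAnnualCompositions:
    def test_single_taxon_share_is_one(self):
        obs = make_observations(
            [("1980-03-01", "only", 4.0), ("1981-09-01", "only", 9.0)],
            [("only", 50.0, "C1")],
        )
        comp = ts.annual_compositions(obs)
        assert np.all(comp.b.to_numpy() == 1.0)

    def test_two_equal_constant_taxa_split_evenly(self):
        rows = []
        for date in ("1980-01-01", "1980-07-01", "1981-12-31"):
            rows += [(date, "a", 3.0), (date, "b", 3.0)]
        obs = make_observations(rows, [("a", 50.0, "CA"), ("b", 50.0, "CB")])
        comp = ts.annual_compositions(obs)
        assert np.allclose(comp.b.to_numpy(), 0.5)
        assert np.allclose(comp.g.to_numpy(), 0.5)
        assert comp.b_bar["a"] == pytest.approx(0.5)

    def test_shares_sum_to_one_every_year(self, default_composition):
        _, _, comp = default_composition
        assert np.abs(comp.b.sum(axis=1) - 1).max() < 1e-12
        assert np.abs(comp.g.sum(axis=1) - 1).max() < 1e-12

    def test_row_order_invariance(self):
        rows = [("1980-01-05", "a", 2.0), ("1980-06-05", "a", 4.0),
                ("1980-01-05", "b", 1.0), ("1980-06-05", "b", 5.0)]
        meta = [("a", 50.0, "C1"), ("b", 60.0, "C2")]
        c1 = ts.annual_compositions(make_observations(rows, meta))
        c2 = ts.annual_compositions(make_observations(rows[::-1], meta))
        pd.testing.assert_frame_equal(c1.b, c2.b)

    def test_merging_same_class_taxa_preserves_class_shares(self, rng):
        dates = pd.date_range("1980-01-01", "1981-12-31", freq="21D")
        rows, merged_rows = [], []
        vals = {t: rng.uniform(1, 10, len(dates)) for t in ("a1", "a2", "b")}
        for i, d in enumerate(dates):
            day = d.strftime("%Y-%m-%d")
            rows += [(day, t, vals[t][i]) for t in ("a1", "a2", "b")]
            merged_rows += [(day, "a", vals["a1"][i] + vals["a2"][i]), (day, "b", vals["b"][i])]
        comp = ts.annual_compositions(
            make_observations(rows, [("a1", 50.0, "CA"), ("a2", 50.0, "CA"), ("b", 50.0, "CB")])
        )
        comp_m = ts.annual_compositions(
            make_observations(merged_rows, [("a", 50.0, "CA"), ("b", 50.0, "CB")])
        )
        assert np.allclose(comp.g.to_numpy(), comp_m.g.to_numpy(), atol=1e-12)

    def test_recovers_generator_shares(self, default_dataset, default_composition):
        """Pipeline-recovered b_iy track the generator's sorting weights."""
        _, _, comp = default_composition
        truth = default_dataset.true_weights[comp.b.columns]
        assert (comp.b - truth).abs().to_numpy().max() < 0.05

    def test_year_without_nearby_observations_errors(self):
        obs = make_observations(
            [("1980-03-01", "a", 1.0), ("1985-03-01", "a", 2.0)],
            [("a", 50.0, "C1")],
        )
        with pytest.raises(ValueError, match="±1 year"):
            ts.annual_compositions(obs)

    def test_leap_year_span_averages_366_days(self):
        # constant value across a leap year: annual mean must be exact
        obs = make_observations(
            [("1968-01-01", "a", 2.0), ("1968-12-31", "a", 2.0)],
            [("a", 50.0, "C1")],
        )
        comp = ts.annual_compositions(obs)
        assert comp.totals[1968] == pytest.approx(2.0, abs=1e-12)

    def test_share_modes_differ_under_covariation(self):
        # taxon a peaks when the community is large: ratio-of-annual-means
        # weights the bloom more than averaged daily shares do
        rows = [("1980-01-01", "a", 1.0), ("1980-07-01", "a", 99.0),
                ("1980-01-01", "b", 9.0), ("1980-07-01", "b", 1.0),
                ("1980-12-31", "a", 1.0), ("1980-12-31", "b", 9.0)]
        meta = [("a", 50.0, "C1"), ("b", 50.0, "C1")]
        daily = ts.annual_compositions(make_observations(rows, meta), share_mode="daily")
        ratio = ts.annual_compositions(make_observations(rows, meta), share_mode="annual_ratio")
        assert ratio.b.loc[1980, "a"] > daily.b.loc[1980, "a"]


class TestClassAggregateAndAverages:
    def test_hand_built_two_year_table(self):
        b = pd.DataFrame(
            {"t1": [0.5, 0.2], "t2": [0.3, 0.3], "t3": [0.2, 0.5]},
            index=pd.Index([1980, 1981], name="year"),
        )
        classes = pd.Series({"t1": "CA", "t2": "CA", "t3": "CB"})
        g = ts.class_aggregate(b, classes)
        assert g.loc[1980, "CA"] == pytest.approx(0.8)
        assert g.loc[1981, "CB"] == pytest.approx(0.5)
        b_bar = ts.long_term_average(b)
        assert b_bar["t1"] == pytest.approx(0.35)

    def test_taxon_without_class_errors(self):
        b = pd.DataFrame({"t1": [1.0]}, index=[1980])
        with pytest.raises(ValueError, match="without class"):
            ts.class_aggregate(b, pd.Series({"t1": ""}))

    def test_absent_taxon_has_zero_long_term_average(self):
        obs = make_observations(
            [("1980-03-01", "a", 1.0), ("1981-03-01", "a", 2.0)],
            [("a", 50.0, "C1"), ("ghost", 50.0, "C1")],
        )
        comp = ts.annual_compositions(obs)
        assert comp.b_bar["ghost"] == 0.0
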