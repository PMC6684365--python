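"""Exposure statistics: summaries, exceedances, day/night split, pooling, mobile."""

from datetime import time

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shsexposure.metrics import (
    AreaSummary,
    MobileMeasurement,
    day_night_medians,
    exceedance_fractions,
    pool_across_prisons,
    summarize_mobile,
    summarize_series,
)
from shsexposure.pm import PMSeries


def _pm(values, start="2016-10-03 00:00", source="P1"):
    idx = pd.date_range(start, periods=len(values), freq="min")
    return PMSeries(source_id=source, pm25=pd.Series(values, index=idx, dtype=float))


class TestSummarizeSeries:
    def test_constant_series(self):
        s = summarize_series(_pm([30.0] * 10))
        assert (s.mean, s.sd, s.maximum, s.duration_minutes) == (30.0, 0.0, 30.0, 10)

    def test_hand_computed_three_points(self):
        s = summarize_series(_pm([10.0, 20.0, 30.0]))
        assert s.mean == pytest.approx(20.0)
        assert s.sd == pytest.approx(10.0)
        assert s.maximum == 30.0

    def test_missing_minutes_excluded_from_duration(self):
        s = summarize_series(_pm([10.0, np.nan, 30.0]))
        assert s.duration_minutes == 2
        assert s.mean == pytest.approx(20.0)


class TestExceedance:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([5.0] * 4, (0.0, 0.0, 0.0)),
            ([30.0] * 4, (100.0, 100.0, 0.0)),
            ([5.0, 15.0, 30.0, 300.0], (75.0, 50.0, 25.0)),
        ],
    )
    def test_enumerated_minutes(self, values, expected):
        assert exceedance_fractions(_pm(values), [10, 25, 246]) == pytest.approx(
            expected
        )

    def test_requires_increasing_thresholds(self):
        with pytest.raises(ValueError):
            exceedance_fractions(_pm([1.0]), [25, 10])

    @given(
        st.lists(
            st.floats(min_value=0, max_value=500, allow_nan=False),
            min_size=1,
            max_size=60,
        ),
        st.floats(min_value=0.1, max_value=50),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_values_and_thresholds(self, values, lift):
        pm = _pm(values)
        base = exceedance_fractions(pm, [10, 25, 246])
        # fractions never increase along increasing thresholds
        assert base[0] >= base[1] >= base[2]
        # raising every value weakly raises every fraction
        lifted = exceedance_fractions(_pm([v + lift for v in values]), [10, 25, 246])
        assert all(b >= a for a, b in zip(base, lifted))


class TestDayNight:
    def test_constant_series_equal_medians(self):
        day, night = day_night_medians(_pm([12.0] * 2880))
        assert day == night == 12.0

    def test_two_level_construction(self):
        idx = pd.date_range("2016-10-03 00:00", periods=1440, freq="min")
        vals = [40.0 if 7 <= t.hour < 23 else 10.0 for t in idx]
        day, night = day_night_medians(
            PMSeries("P1", pd.Series(vals, index=idx)), (time(7), time(23))
        )
        assert (day, night) == (40.0, 10.0)

    def test_partition_covers_each_minute_once(self):
        idx = pd.date_range("2016-10-03 00:00", periods=1440, freq="min")
        clock = idx.time
        is_day = (clock >= time(7)) & (clock < time(23))
        assert int(is_day.sum()) + int((~is_day).sum()) == 1440
        assert int(is_day.sum()) == 16 * 60

    def test_single_class_series_reports_other_absent(self):
        day, night = day_night_medians(_pm([5.0] * 60, start="2016-10-03 12:00"))
        assert day == 5.0 and night is None


class TestPooling:
    def test_median_of_survey_means(self, area_survey):
        summaries = [
            AreaSummary(
                prison_id=r["prison"],
                duration_minutes=int(r["duration_min"]),
                mean=r["mean_pm"],
                sd=r["sd_pm"],
                maximum=r["max_pm"],
            )
            for _, r in area_survey.iterrows()
        ]
        pooled = pool_across_prisons(summaries)
        assert pooled["mean"] == pytest.approx(31.7)
        assert pooled["maximum"] == pytest.approx(171.0)

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1000, allow_nan=False),
            min_size=1,
            max_size=25,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_sort_based_median_oracle(self, means):
        summaries = [
            AreaSummary(f"P{i}", 10, m, 0.0, m) for i, m in enumerate(means)
        ]
        pooled = pool_across_prisons(summaries)
        v = sorted(means)
        n = len(v)
        oracle = v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2.0
        assert pooled["mean"] == pytest.approx(oracle)


class TestMobile:
    def test_singleton_category_degenerate(self):
        table, _ = summarize_mobile(
            [
                MobileMeasurement("P1", "reception", 30, 2.4),
                MobileMeasurement("P2", "recreation", 30, 72.2),
            ]
        )
        row = table.set_index("category").loc["reception"]
        assert row["median"] == row["mean"] == row["min"] == row["max"] == 2.4
        assert row["p25"] == row["p75"] == 2.4

    def test_reception_pair_hand_computed(self):
        table, _ = summarize_mobile(
            [
                MobileMeasurement("P1", "reception", 30, 1.0),
                MobileMeasurement("P2", "reception", 30, 4.1),
            ]
        )
        row = table.iloc[0]
        assert (row["min"], row["max"]) == (1.0, 4.1)
        assert row["mean"] == pytest.approx(2.55)

    def test_rows_ordered_by_median(self):
        table, _ = summarize_mobile(
            [
                MobileMeasurement("P1", "recreation", 30, 72.2),
                MobileMeasurement("P1", "reception", 30, 2.4),
                MobileMeasurement("P1", "workshop", 30, 19.1),
            ]
        )
        assert table["median"].is_monotonic_increasing

    def test_pooled_gm_gsd_recovered_from_lognormal_sample(self):
        rng = np.random.default_rng(42)
        vals = rng.lognormal(np.log(24.0), np.log(4.0), 86)
        ms = [MobileMeasurement("P1", "workshop", 30, v) for v in vals]
        _, (gm, gsd) = summarize_mobile(ms)
        # sampling envelope at n=86: GM within 25% of the generating value
        assert abs(gm - 24.0) / 24.0 < 0.25

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            MobileMeasurement("P1", "spaceport", 30, 1.0)

    def test_nonpositive_mean_breaks_gm(self):
        with pytest.raises(ValueError, match="positive"):
            summarize_mobile([MobileMeasurement("P1", "reception", 30, 0.0)])
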