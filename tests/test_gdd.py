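"""Thermal-time accounting: examples and accumulation invariants."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from weedcomp import (
    StageCalendar,
    TemperatureSeries,
    accumulate_gdd,
    daily_gdd,
    stage_summary,
)
from weedcomp.exceptions import DomainError, RangeError


def make_series(t_values, start="2014-06-01", regime="A", year=2014):
    t = np.asarray(t_values, dtype=float)
    dates = pd.date_range(start, periods=len(t), freq="D")
    return TemperatureSeries(regime_label=regime, year=year, dates=dates, t_mean=t)


temps = st.floats(min_value=-15.0, max_value=45.0, allow_nan=False, width=32)


class TestDailyGdd:
    @pytest.mark.parametrize(
        "t_mean, t_base, expected",
        [(24.1, 10, 14.1), (10, 10, 0.0), (8, 10, 0.0), (35.5, 10, 25.5)],
    )
    def test_examples(self, t_mean, t_base, expected):
        assert daily_gdd(t_mean, t_base) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            daily_gdd(float("nan"))

    @given(t=temps, base=st.floats(0, 20, allow_nan=False))
    def test_never_negative_and_clamped(self, t, base):
        g = daily_gdd(t, base)
        assert g >= 0
        assert g == pytest.approx(max(t - base, 0.0))


class TestAccumulateGdd:
    def test_constant_series_matches_mean_times_days(self):
        s = make_series([24.1] * 89)
        g = accumulate_gdd(s, s.start, s.end, 10.0)
        assert g.gdd == pytest.approx(1254.9)
        assert g.n_days == 89

    def test_at_base_temperature_is_zero(self):
        s = make_series([10.0] * 30)
        assert accumulate_gdd(s, s.start, s.end, 10.0).gdd == 0.0

    def test_piecewise_hand_sum(self):
        # daily clamping: 15 + 0 + 20
        s = make_series([25.0, 9.0, 30.0])
        assert accumulate_gdd(s, s.start, s.end, 10.0).gdd == pytest.approx(35.0)

    def test_window_outside_span_raises(self):
        s = make_series([20.0] * 10)
        with pytest.raises(RangeError):
            accumulate_gdd(s, s.start - pd.Timedelta("1D"), s.end)
        with pytest.raises(RangeError):
            accumulate_gdd(s, s.end, s.start)

    @given(t=st.lists(temps, min_size=3, max_size=40))
    def test_additivity_over_contiguous_windows(self, t):
        s = make_series(t)
        split = s.dates[len(t) // 2]
        left = accumulate_gdd(s, s.start, split).gdd
        right = accumulate_gdd(s, split + pd.Timedelta("1D"), s.end).gdd
        total = accumulate_gdd(s, s.start, s.end).gdd
        assert left + right == pytest.approx(total, abs=1e-9)

    @given(
        t=st.lists(temps, min_size=2, max_size=30),
        idx=st.integers(0, 29),
        bump=st.floats(0.0, 20.0, allow_nan=False),
    )
    def test_monotone_in_any_days_temperature(self, t, idx, bump):
        idx = idx % len(t)
        s = make_series(t)
        warmer = list(t)
        warmer[idx] = warmer[idx] + bump
        s2 = make_series(warmer)
        assert (
            accumulate_gdd(s2, s2.start, s2.end).gdd
            >= accumulate_gdd(s, s.start, s.end).gdd
        )

    @given(t=st.lists(temps, min_size=1, max_size=40))
    def test_non_negative_for_any_temperatures(self, t):
        s = make_series(t)
        assert accumulate_gdd(s, s.start, s.end).gdd >= 0.0


class TestStageSummary:
    def test_constant_series_means(self):
        cal = StageCalendar.default(2014)
        n = (cal.maturity - cal.transplanting).days + 1
        s = make_series([24.1] * n)
        summary = stage_summary(s, cal)
        assert np.allclose(summary["mean_t_c"], 24.1)
        # 89-day flowering window at constant 24.1
        assert summary.loc["to_flowering", "gdd"] == pytest.approx(14.1 * 89)

    def test_nested_windows_weakly_increasing(self):
        cal = StageCalendar.default(2014)
        n = (cal.maturity - cal.transplanting).days + 1
        rng = np.random.default_rng(0)
        s = make_series(15.0 + 10 * rng.random(n))
        g = stage_summary(s, cal)["gdd"]
        assert g["to_tillering"] <= g["to_flowering"] <= g["to_maturity"]

    def test_uniform_offset_adds_offset_times_days(self):
        cal = StageCalendar.default(2014)
        n = (cal.maturity - cal.transplanting).days + 1
        day = np.arange(n)
        base = 20.0 + 5.0 * np.sin(2 * np.pi * day / 365.0)  # always above t_base
        s0 = make_series(base)
        s5 = make_series(base + 5.0)
        g0 = stage_summary(s0, cal)
        g5 = stage_summary(s5, cal)
        for label in g0.index:
            n_days = g0.loc[label, "n_days"]
            assert g5.loc[label, "gdd"] - g0.loc[label, "gdd"] == pytest.approx(
                5.0 * n_days
            )


class TestValidation:
    def test_non_contiguous_dates_rejected(self):
        dates = pd.DatetimeIndex(["2014-06-01", "2014-06-03"])
        with pytest.raises(ValueError):
            TemperatureSeries("A", 2014, dates, np.array([20.0, 21.0]))

    def test_misordered_calendar_rejected(self):
        with pytest.raises(ValueError):
            StageCalendar(
                transplanting=dt.date(2014, 6, 1),
                tillering=dt.date(2014, 5, 1),
                flowering=dt.date(2014, 8, 28),
                maturity=dt.date(2014, 10, 15),
            )
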