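from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from phenosignal.phenology import (
    CensusSeries,
    SiteCalendar,
    TemperatureSeries,
    augspurger_synchrony,
    calendar_traits,
    daily_extremes,
    double_sine_day,
    gdd_double_sine,
    gdd_traits,
)


def hourly_series(day_temps, start=date(2018, 10, 1), site="s"):
    """Build an hourly series from a list of per-day (callable hour->temp)."""
    rows = []
    for d, fn in enumerate(day_temps):
        for h in range(24):
            rows.append(
                {
                    "timestamp": datetime.combine(
                        start + timedelta(days=d), datetime.min.time()
                    )
                    + timedelta(hours=h),
                    "temp_c": fn(h),
                }
            )
    return TemperatureSeries(site, pd.DataFrame(rows))


class TestDailyExtremes:
    def test_constant_day(self):
        ext = daily_extremes(hourly_series([lambda h: 15.0]))
        assert ext.loc[0, "tmin"] == 15.0 and ext.loc[0, "tmax"] == 15.0
        assert not ext.loc[0, "flagged"]

    def test_sinusoid_day(self):
        fn = lambda h: 5 - 5 * np.cos(2 * np.pi * (h - 5) / 24)  # min 0 @05, max 10 @17
        ext = daily_extremes(hourly_series([fn]))
        assert ext.loc[0, "tmin"] == pytest.approx(0.0, abs=0.2)
        assert ext.loc[0, "tmax"] == pytest.approx(10.0, abs=0.2)

    def test_sparse_day_flagged(self):
        ts = TemperatureSeries(
            "s",
            pd.DataFrame(
                {"timestamp": [datetime(2018, 10, 1, 12)], "temp_c": [7.0]}
            ),
        )
        ext = daily_extremes(ts)
        assert ext.loc[0, "flagged"]
        assert ext.loc[0, "tmin"] == ext.loc[0, "tmax"] == 7.0

    def test_empty_series_error(self):
        with pytest.raises(ValueError, match="empty"):
            daily_extremes(
                TemperatureSeries("s", pd.DataFrame(columns=["timestamp", "temp_c"]))
            )


class TestDoubleSine:
    def test_constant_day_closed_form(self):
        # flat 15 C at base 5: (15-5) degree-days
        assert double_sine_day(15, 15, 15, 5.0) == pytest.approx(10.0)

    def test_day_below_base_contributes_zero(self):
        assert double_sine_day(-5, 4.9, -5, 5.0) == 0.0

    def test_partial_clip_matches_numerical_integral(self):
        # frozen from a fine-grid integration of the two clipped half-sines
        assert double_sine_day(0, 10, 0, 5.0) == pytest.approx(5 / np.pi, abs=1e-9)

    def test_random_days_match_numerical_integral(self):
        gen = np.random.default_rng(2)
        grid = np.linspace(-np.pi / 2, np.pi / 2, 20001)
        for _ in range(1000):
            tl = gen.uniform(-10, 20)
            th = tl + gen.uniform(0, 25)
            base = gen.uniform(-5, 15)
            m, a = (th + tl) / 2, (th - tl) / 2
            profile = np.maximum(m + a * np.sin(grid) - base, 0.0)
            oracle = 2 * np.trapezoid(profile, grid) / (2 * np.pi)
            assert double_sine_day(tl, th, tl, base) == pytest.approx(
                oracle, abs=0.01
            )

    def test_cumulative_nondecreasing_and_base_ordering(self):
        gen = np.random.default_rng(4)
        days = [
            (lambda h, o=o, a=a: o + a * np.sin(2 * np.pi * h / 24))
            for o, a in zip(gen.uniform(-5, 15, 30), gen.uniform(0, 8, 30))
        ]
        ext = daily_extremes(hourly_series(days))
        start, end = ext["date"].iloc[0], ext["date"].iloc[-1]
        g0 = gdd_double_sine(ext, 0.0, start, end)
        g5 = gdd_double_sine(ext, 5.0, start, end)
        assert (g0.diff().dropna() >= -1e-12).all()
        assert (g0 >= g5 - 1e-12).all()

    def test_missing_day_error(self):
        ext = daily_extremes(hourly_series([lambda h: 10.0]))
        with pytest.raises(ValueError, match="missing"):
            gdd_double_sine(ext, 0.0, date(2018, 10, 1), date(2018, 10, 5))


def census(site, species, entries, start=date(2018, 9, 11)):
    return CensusSeries(
        site,
        species,
        pd.DataFrame(
            {
                "date": [start + timedelta(days=d) for d, _, _ in entries],
                "n_plants": [p for _, p, _ in entries],
                "n_flowers": [f for _, _, f in entries],
            }
        ),
    )


class TestCalendarTraits:
    def test_first_flowering(self):
        cal = SiteCalendar("s", date(2018, 9, 11), date(2019, 1, 1))
        # DOY of 2018-09-11 is 254; first flowering on DOY 280 = +26 days
        cs = census("s", "sp", [(20, 0, 0), (26, 2, 5), (31, 1, 2)])
        tr = calendar_traits(cs, cal)
        assert tr["FF_DOY"] == 280.0
        assert tr["FF"] == 26.0

    def test_peak_tie_breaks_early(self):
        cal = SiteCalendar("s", date(2018, 9, 11), date(2019, 1, 1))
        cs = census("s", "sp", [(0, 1, 1), (5, 3, 9), (10, 3, 9), (15, 1, 1)])
        tr = calendar_traits(cs, cal)
        assert tr["PFP"] == 5.0 and tr["PFA"] == 5.0

    def test_season_length(self):
        cal = SiteCalendar("s", date(2018, 9, 11), date(2019, 1, 1))
        cs = census("s", "sp", [(26, 1, 1), (36, 0, 0), (46, 2, 2)])
        assert calendar_traits(cs, cal)["FSL"] == 20.0

    def test_never_flowering_returns_none(self):
        cal = SiteCalendar("s", date(2018, 9, 11), date(2019, 1, 1))
        assert calendar_traits(census("s", "sp", [(0, 0, 0), (5, 0, 0)]), cal) is None

    def test_onset_never_after_peaks(self):
        gen = np.random.default_rng(8)
        cal = SiteCalendar("s", date(2018, 9, 11), date(2019, 1, 1))
        for _ in range(200):
            counts = gen.poisson(2.0, size=10)
            if counts.sum() == 0:
                continue
            cs = census(
                "s", "sp", [(5 * i, int(c), int(c * 3)) for i, c in enumerate(counts)]
            )
            tr = calendar_traits(cs, cal)
            assert tr["FF"] <= tr["PFP"] and tr["FF"] <= tr["PFA"]


class TestGddTraits:
    def test_constant_temperature_closed_form(self):
        # 10 constant 10 C days: each contributes 10 GDD0 and 5 GDD5
        ext = daily_extremes(hourly_series([lambda h: 10.0] * 10))
        cal = SiteCalendar("s", date(2018, 10, 1), date(2018, 10, 10))
        g0 = gdd_double_sine(ext, 0.0, cal.snowmelt_date, cal.season_end)
        g5 = gdd_double_sine(ext, 5.0, cal.snowmelt_date, cal.season_end)
        tr = gdd_traits({"FF": 4.0, "PFP": 4.0, "PFA": 9.0}, cal, g0, g5)
        assert tr["GDD0FF"] == pytest.approx(50.0)
        assert tr["GDD5FF"] == pytest.approx(25.0)
        assert tr["GDD0PFA"] == pytest.approx(100.0)

    def test_all_below_base_gives_zero(self):
        ext = daily_extremes(hourly_series([lambda h: 3.0] * 5))
        cal = SiteCalendar("s", date(2018, 10, 1), date(2018, 10, 5))
        g0 = gdd_double_sine(ext, 0.0, cal.snowmelt_date, cal.season_end)
        g5 = gdd_double_sine(ext, 5.0, cal.snowmelt_date, cal.season_end)
        tr = gdd_traits({"FF": 2.0, "PFP": 2.0, "PFA": 2.0}, cal, g0, g5)
        assert tr["GDD5FF"] == 0.0 and tr["GDD5PFA"] == 0.0

    def test_milestone_before_snowmelt_error(self):
        ext = daily_extremes(hourly_series([lambda h: 10.0] * 5))
        cal = SiteCalendar("s", date(2018, 10, 1), date(2018, 10, 5))
        g = gdd_double_sine(ext, 0.0, cal.snowmelt_date, cal.season_end)
        with pytest.raises(ValueError, match="biofix"):
            gdd_traits({"FF": -1.0, "PFP": 0.0, "PFA": 0.0}, cal, g, g)


class TestSynchrony:
    def test_identical_schedules(self):
        P = pd.DataFrame([[1, 1, 0], [1, 1, 0]], index=["a", "b"]).astype(bool)
        per, site = augspurger_synchrony(P)
        assert per.tolist() == [1.0, 1.0] and site == 1.0

    def test_disjoint_schedules(self):
        P = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"]).astype(bool)
        _, site = augspurger_synchrony(P)
        assert site == 0.0

    def test_half_overlap(self):
        # a flowers on censuses 1-4, b on 3-6: e_ab = 2, f = 4 each
        P = pd.DataFrame(
            [[1, 1, 1, 1, 0, 0], [0, 0, 1, 1, 1, 1]], index=["a", "b"]
        ).astype(bool)
        per, site = augspurger_synchrony(P)
        assert per["a"] == 0.5 and per["b"] == 0.5 and site == 0.5

    def test_invariant_to_empty_censuses_and_relabeling(self):
        gen = np.random.default_rng(1)
        P = pd.DataFrame(
            gen.integers(0, 2, size=(5, 8)).astype(bool),
            index=list("abcde"),
        )
        P = P[P.sum(axis=1) > 0]
        _, site = augspurger_synchrony(P)
        padded = pd.concat(
            [P, pd.DataFrame(False, index=P.index, columns=["x1", "x2"])], axis=1
        )
        _, site_padded = augspurger_synchrony(padded)
        shuffled = P[list(gen.permutation(P.columns))]
        _, site_shuffled = augspurger_synchrony(shuffled)
        assert site == pytest.approx(site_padded) == pytest.approx(site_shuffled)

    def test_values_in_unit_interval(self):
        gen = np.random.default_rng(6)
        for _ in range(50):
            P = pd.DataFrame(gen.integers(0, 2, size=(6, 10)).astype(bool))
            P = P[P.sum(axis=1) > 0]
            if len(P) < 2:
                continue
            per, site = augspurger_synchrony(P)
            assert ((per >= 0) & (per <= 1)).all() and 0 <= site <= 1
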