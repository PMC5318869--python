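import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from awpm.weather import (HETAO, ClimateNormals, WeatherDay, daylength_hours,
                          et0_penman_monteith, generate_weather, read_weather,
                          solar_radiation, write_weather)


# ---------------------------------------------------------------------------
# independent FAO-56 oracle, coded step by step from the worked procedure
# ---------------------------------------------------------------------------

def fao56_reference_et0(date, tmax, tmin, sunshine, rh_mean, wind,
                        lat_deg, elev_m):
    doy = date.timetuple().tm_yday
    phi = math.radians(lat_deg)
    # step 1: slope of the saturation vapour pressure curve
    tmean = (tmax + tmin) / 2
    svp = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
    slope = 4098 * svp(tmean) / (tmean + 237.3) ** 2
    # step 2: psychrometric constant from atmospheric pressure
    press = 101.3 * ((293 - 0.0065 * elev_m) / 293) ** 5.26
    psy = 0.000665 * press
    # step 3: vapour pressure deficit from mean relative humidity
    es = (svp(tmax) + svp(tmin)) / 2
    ea = rh_mean / 100 * es
    # step 4: radiation balance from sunshine via Angstrom
    dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    decl = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    ws = math.acos(-math.tan(phi) * math.tan(decl))
    ra = 24 * 60 / math.pi * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(decl)
        + math.cos(phi) * math.cos(decl) * math.sin(ws))
    nmax = 24 / math.pi * ws
    rs = (0.25 + 0.50 * min(sunshine, nmax) / nmax) * ra
    rso = (0.75 + 2e-5 * elev_m) * ra
    rns = 0.77 * rs
    rnl = 4.903e-9 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2 \
        * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * min(rs / rso, 1.0) - 0.35)
    rn = rns - rnl
    # step 5: combination equation, G = 0 at daily step
    et0 = (0.408 * slope * rn
           + psy * 900 / (tmean + 273) * wind * (es - ea)) \
        / (slope + psy * (1 + 0.34 * wind))
    return max(0.0, et0)


class TestReadWrite:
    def _rows(self):
        return [
            WeatherDay(dt.date(2007, 6, 1), 25.0, 11.0, rh_mean=40.0,
                       wind2m=2.0, rain=0.0, sunshine=9.0),
            WeatherDay(dt.date(2007, 6, 2), 27.5, 12.5, rh_mean=42.0,
                       wind2m=1.5, rain=3.2, sunshine=7.5),
            WeatherDay(dt.date(2007, 6, 3), 24.0, 13.0, rh_mean=60.0,
                       wind2m=3.0, rain=0.4, sunshine=5.0),
        ]

    def test_three_line_file_parses(self, tmp_path):
        path = tmp_path / "w.csv"
        write_weather(path, self._rows())
        days = read_weather(path)
        assert len(days) == 3
        assert days[0].date == dt.date(2007, 6, 1)

    def test_roundtrip_identity(self, tmp_path):
        path = tmp_path / "w.csv"
        rows = self._rows()
        write_weather(path, rows)
        back = read_weather(path)
        for a, b in zip(rows, back):
            assert a == b

    def test_roundtrip_synthetic_lossless(self, tmp_path, synthetic_season):
        path = tmp_path / "season.csv"
        write_weather(path, synthetic_season)
        back = read_weather(path)
        assert len(back) == len(synthetic_season)
        for a, b in zip(synthetic_season, back):
            for f in ("tmax", "tmin", "sunshine", "rh_mean", "wind2m", "rain"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_tmax_below_tmin_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("date,tmax,tmin,sunshine,rh,wind,rain\n"
                        "2007-06-01,25,11,9,40,2,0\n"
                        "2007-06-02,10,12,9,40,2,0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_weather(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("date,tmax,tmin,rh,wind,rain\n2007-06-01,25,11,40,2,0\n")
        with pytest.raises(ValueError, match="missing column"):
            read_weather(path)

    def test_date_gap_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("date,tmax,tmin,sunshine,rh,wind,rain\n"
                        "2007-06-01,25,11,9,40,2,0\n"
                        "2007-06-03,25,11,9,40,2,0\n")
        with pytest.raises(ValueError, match="non-contiguous"):
            read_weather(path)

    def test_radiation_column_accepted(self, tmp_path):
        path = tmp_path / "rad.csv"
        path.write_text("date,tmax,tmin,radiation,rh,wind,rain\n"
                        "2007-06-01,25,11,22.5,40,2,0\n")
        (day,) = read_weather(path)
        assert day.radiation == 22.5
        assert day.sunshine is None


class TestWeatherDayInvariants:
    def test_both_sunshine_and_radiation_rejected(self):
        with pytest.raises(ValueError):
            WeatherDay(dt.date(2007, 6, 1), 25, 11, rh_mean=40, wind2m=2,
                       rain=0, sunshine=9, radiation=20)

    def test_neither_rejected(self):
        with pytest.raises(ValueError):
            WeatherDay(dt.date(2007, 6, 1), 25, 11, rh_mean=40, wind2m=2,
                       rain=0)

    @pytest.mark.parametrize("kwargs", [
        {"rain": -1.0}, {"rh_mean": 130.0}, {"wind2m": -0.5},
    ])
    def test_bad_values_rejected(self, kwargs):
        base = dict(date=dt.date(2007, 6, 1), tmax=25.0, tmin=11.0,
                    rh_mean=40.0, wind2m=2.0, rain=0.0, sunshine=9.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            WeatherDay(**base)


class TestET0:
    def test_matches_independent_fao56_oracle(self, midsummer_day, hetao):
        got = et0_penman_monteith(midsummer_day, hetao)
        want = fao56_reference_et0(
            midsummer_day.date, midsummer_day.tmax, midsummer_day.tmin,
            midsummer_day.sunshine, midsummer_day.rh_mean,
            midsummer_day.wind2m, hetao.latitude, hetao.elevation)
        assert got == pytest.approx(want, abs=0.05)

    def test_zero_driving_terms(self, hetao):
        # saturated, calm air and no shortwave: no evaporative demand
        day = WeatherDay(dt.date(2007, 7, 1), 20.0, 20.0, rh_mean=100.0,
                         wind2m=0.0, rain=0.0, radiation=0.0)
        assert et0_penman_monteith(day, hetao) == 0.0

    def test_wind_monotone_under_vpd(self, midsummer_day, hetao):
        windy = WeatherDay(midsummer_day.date, midsummer_day.tmax,
                           midsummer_day.tmin, rh_mean=midsummer_day.rh_mean,
                           wind2m=2 * midsummer_day.wind2m, rain=0.0,
                           sunshine=midsummer_day.sunshine)
        assert et0_penman_monteith(windy, hetao) \
            > et0_penman_monteith(midsummer_day, hetao)

    @given(
        doy=st.integers(1, 365),
        tmin=st.floats(-20, 30),
        dtr=st.floats(0, 25),
        sun_frac=st.floats(0, 1),
        rh=st.floats(0, 100),
        wind=st.floats(0, 15),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_for_all_valid_days(self, doy, tmin, dtr, sun_frac,
                                            rh, wind):
        date = dt.date(2007, 1, 1) + dt.timedelta(days=doy - 1)
        n = daylength_hours(date, HETAO.latitude)
        day = WeatherDay(date, tmin + dtr, tmin, rh_mean=rh, wind2m=wind,
                         rain=0.0, sunshine=sun_frac * n)
        assert et0_penman_monteith(day, HETAO) >= 0.0


class TestGenerator:
    def test_same_seed_identical(self, season_2007):
        start, end = season_2007
        a = generate_weather(HETAO, start, end, seed=42)
        b = generate_weather(HETAO, start, end, seed=42)
        assert a == b

    def test_different_seed_differs(self, season_2007):
        start, end = season_2007
        a = generate_weather(HETAO, start, end, seed=1)
        b = generate_weather(HETAO, start, end, seed=2)
        assert a != b

    def test_rain_total_exact(self, synthetic_season):
        total = sum(d.rain for d in synthetic_season)
        assert total == pytest.approx(128.0, abs=1e-9)

    def test_july_august_concentration(self):
        # >= 70% of rain in July-August across seeds, per the preset
        start, end = dt.date(2007, 4, 20), dt.date(2007, 9, 24)
        for seed in range(20):
            days = generate_weather(HETAO, start, end, seed=seed)
            jul_aug = sum(d.rain for d in days if d.date.month in (7, 8))
            assert jul_aug / 128.0 >= 0.70 - 1e-9
            assert sum(d.rain for d in days) == pytest.approx(128.0, abs=1e-9)

    def test_mean_july_temperature_ensemble(self):
        # Monte-Carlo: ensemble-mean July tmean close to the 23.8 degC normal
        start, end = dt.date(2007, 6, 15), dt.date(2007, 8, 15)
        means = []
        for seed in range(1000):
            days = generate_weather(HETAO, start, end, seed=seed)
            july = [d.tmean for d in days if d.date.month == 7]
            means.append(np.mean(july))
        assert abs(np.mean(means) - 23.8) < 1.5

    def test_tmax_ge_tmin_always(self, synthetic_season):
        assert all(d.tmax >= d.tmin for d in synthetic_season)

    def test_sunshine_within_daylength(self, synthetic_season, hetao):
        for d in synthetic_season:
            assert 0 <= d.sunshine <= daylength_hours(d.date, hetao.latitude)

    def test_empty_season_rejected(self):
        with pytest.raises(ValueError):
            generate_weather(HETAO, dt.date(2007, 6, 2), dt.date(2007, 6, 1), 1)

    def test_cross_year_rejected(self):
        with pytest.raises(ValueError):
            generate_weather(HETAO, dt.date(2007, 11, 1), dt.date(2008, 2, 1), 1)


class TestNormals:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ClimateNormals(monthly_tmean=(0.0,) * 12,
                           monthly_rain_fraction=(0.1,) * 12,
                           seasonal_rain_mm=100.0, latitude=40.0,
                           elevation=1000.0)

    def test_hetao_july_august_fraction(self, hetao):
        assert hetao.monthly_rain_fraction[6] + hetao.monthly_rain_fraction[7] >= 0.70
        assert hetao.monthly_tmean[0] == -10.1
        assert hetao.monthly_tmean[6] == 23.8
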