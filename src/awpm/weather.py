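"""Daily weather I/O, FAO-56 reference evapotranspiration, synthetic forcing.

Units used throughout the package: per-day water fluxes in mm d-1, depths
below the surface in cm (positive downward), temperatures in degC,
radiation in MJ m-2 d-1.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WeatherDay", "ClimateNormals", "HETAO", "read_weather", "write_weather",
    "daylength_hours", "extraterrestrial_radiation", "solar_radiation",
    "et0_penman_monteith", "generate_weather",
]

# FAO-56 constants
_GSC = 0.0820          # solar constant, MJ m-2 min-1
_SIGMA = 4.903e-9      # Stefan-Boltzmann, MJ K-4 m-2 d-1
_ANGSTROM_A = 0.25
_ANGSTROM_B = 0.50


@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological forcing.

    Exactly one of ``sunshine`` (bright-sunshine hours) or ``radiation``
    (incoming shortwave, MJ m-2 d-1) must be present.
    """

    date: dt.date
    tmax: float
    tmin: float
    rh_mean: float
    wind2m: float
    rain: float
    sunshine: float | None = None
    radiation: float | None = None

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.rain < 0:
            raise ValueError(f"{self.date}: negative rain ({self.rain})")
        if not 0.0 <= self.rh_mean <= 100.0:
            raise ValueError(f"{self.date}: rh_mean outside [0, 100]")
        if self.wind2m < 0:
            raise ValueError(f"{self.date}: negative wind speed")
        if (self.sunshine is None) == (self.radiation is None):
            raise ValueError(
                f"{self.date}: exactly one of sunshine/radiation required"
            )
        if self.sunshine is not None and self.sunshine < 0:
            raise ValueError(f"{self.date}: negative sunshine hours")
        if self.radiation is not None and self.radiation < 0:
            raise ValueError(f"{self.date}: negative radiation")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class ClimateNormals:
    """Monthly climate normals plus site geometry for ET0 and synthesis."""

    monthly_tmean: tuple[float, ...]       # degC, Jan..Dec
    monthly_rain_fraction: tuple[float, ...]  # sums to 1
    seasonal_rain_mm: float
    latitude: float                        # degrees, +N
    elevation: float                       # m above sea level
    diurnal_range: float = 12.0            # mean tmax - tmin, degC
    mean_sunshine_fraction: float = 0.70   # n/N climatology
    mean_rh: float = 50.0                  # %
    mean_wind: float = 2.0                 # m s-1 at 2 m

    def __post_init__(self) -> None:
        if len(self.monthly_tmean) != 12 or len(self.monthly_rain_fraction) != 12:
            raise ValueError("normals need 12 monthly values")
        if any(f < 0 for f in self.monthly_rain_fraction):
            raise ValueError("rain fractions must be non-negative")
        if abs(sum(self.monthly_rain_fraction) - 1.0) > 1e-9:
            raise ValueError("rain fractions must sum to 1")


#: Hetao irrigation district (arid continental, Inner Mongolia): monthly mean
#: temperature runs from -10.1 degC in January to 23.8 degC in July, with the
#: bulk (>70%) of rain falling in July-August.
HETAO = ClimateNormals(
    monthly_tmean=(-10.1, -6.5, 1.5, 9.5, 16.5, 21.5, 23.8, 21.9, 15.5,
                   7.5, -1.5, -8.5),
    monthly_rain_fraction=(0.005, 0.005, 0.01, 0.02, 0.04, 0.10, 0.40,
                           0.32, 0.06, 0.02, 0.01, 0.01),
    seasonal_rain_mm=128.0,
    latitude=40.8,
    elevation=1040.0,
    diurnal_range=13.0,
    mean_sunshine_fraction=0.62,
    mean_rh=60.0,
    mean_wind=1.7,
)

_COLUMNS = ("date", "tmax", "tmin", "sunshine", "rh", "wind", "rain")


def read_weather(path, dialect: dict[str, str] | None = None) -> list[WeatherDay]:
    """Read a comma-delimited daily weather file.

    The header must name ``date,tmax,tmin,sunshine,rh,wind,rain`` (a
    ``radiation`` column may replace ``sunshine``); *dialect* maps these
    canonical names to the actual column names in the file. Dates must be
    ISO-8601, strictly increasing and gap-free.
    """
    dialect = dialect or {}
    colname = {k: dialect.get(k, k) for k in _COLUMNS + ("radiation",)}
    days: list[WeatherDay] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        have = set(reader.fieldnames)
        use_radiation = colname["radiation"] in have
        required = [colname[k] for k in ("date", "tmax", "tmin", "rh", "wind", "rain")]
        required.append(colname["radiation"] if use_radiation else colname["sunshine"])
        missing = [c for c in required if c not in have]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                date = dt.date.fromisoformat(row[colname["date"]].strip())
                kwargs = dict(
                    date=date,
                    tmax=float(row[colname["tmax"]]),
                    tmin=float(row[colname["tmin"]]),
                    rh_mean=float(row[colname["rh"]]),
                    wind2m=float(row[colname["wind"]]),
                    rain=float(row[colname["rain"]]),
                )
                if use_radiation:
                    kwargs["radiation"] = float(row[colname["radiation"]])
                else:
                    kwargs["sunshine"] = float(row[colname["sunshine"]])
                day = WeatherDay(**kwargs)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from exc
            if days:
                expected = days[-1].date + dt.timedelta(days=1)
                if day.date != expected:
                    raise ValueError(
                        f"{path}, line {i}: non-contiguous date {day.date}, "
                        f"expected {expected}"
                    )
            days.append(day)
    return days


def write_weather(path, days: Iterable[WeatherDay]) -> None:
    """Write days to a comma-delimited file readable by :func:`read_weather`."""
    days = list(days)
    use_radiation = days and days[0].radiation is not None
    header = list(_COLUMNS)
    if use_radiation:
        header[3] = "radiation"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for d in days:
            sun = d.radiation if use_radiation else d.sunshine
            writer.writerow([d.date.isoformat(),
                             repr(d.tmax), repr(d.tmin), repr(sun),
                             repr(d.rh_mean), repr(d.wind2m), repr(d.rain)])


# ---------------------------------------------------------------------------
# FAO-56 Penman-Monteith
# ---------------------------------------------------------------------------

def _solar_geometry(date: dt.date, latitude: float) -> tuple[float, float, float]:
    """Return (Ra, N, doy): extraterrestrial radiation MJ m-2 d-1, daylength h."""
    doy = date.timetuple().tm_yday
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (24.0 * 60.0 / math.pi) * _GSC * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    n_hours = 24.0 / math.pi * ws
    return ra, n_hours, doy


def daylength_hours(date: dt.date, latitude: float) -> float:
    """Astronomical daylength N (hours)."""
    return _solar_geometry(date, latitude)[1]


def extraterrestrial_radiation(date: dt.date, latitude: float) -> float:
    """Extraterrestrial radiation Ra (MJ m-2 d-1)."""
    return _solar_geometry(date, latitude)[0]


def solar_radiation(day: WeatherDay, site: ClimateNormals) -> float:
    """Incoming shortwave radiation Rs (MJ m-2 d-1).

    Uses the day's measured radiation when present, otherwise the Angstrom
    formula Rs = (a + b n/N) Ra with a=0.25, b=0.50.
    """
    if day.radiation is not None:
        return day.radiation
    ra, n_hours, _ = _solar_geometry(day.date, site.latitude)
    n = min(day.sunshine, n_hours)
    return (_ANGSTROM_A + _ANGSTROM_B * n / n_hours) * ra


def _sat_vp(t: float) -> float:
    """Saturation vapour pressure (kPa) at temperature t (degC)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def et0_penman_monteith(day: WeatherDay, site: ClimateNormals) -> float:
    """FAO-56 Penman-Monteith grass reference evapotranspiration (mm d-1).

    Daily formulation with soil heat flux G = 0; psychrometric constant
    from site elevation; actual vapour pressure from mean relative
    humidity; net longwave from the clear-sky ratio. Result is clipped at
    zero (condensation is not credited).
    """
    t = day.tmean
    ra, n_hours, _ = _solar_geometry(day.date, site.latitude)
    rs = solar_radiation(day, site)
    rso = (0.75 + 2e-5 * site.elevation) * ra
    rns = (1.0 - 0.23) * rs

    es = 0.5 * (_sat_vp(day.tmax) + _sat_vp(day.tmin))
    ea = day.rh_mean / 100.0 * es
    rel = min(rs / rso, 1.0) if rso > 0 else 0.0
    cloud = max(1.35 * rel - 0.35, 0.0)  # no net longwave gain on overcast days
    rnl = _SIGMA * 0.5 * ((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4) \
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0))) * cloud
    rn = rns - rnl

    pressure = 101.3 * ((293.0 - 0.0065 * site.elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    delta = 4098.0 * _sat_vp(t) / (t + 237.3) ** 2

    num = 0.408 * delta * rn + gamma * 900.0 / (t + 273.0) * day.wind2m * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * day.wind2m)
    return max(0.0, num / den)


# ---------------------------------------------------------------------------
# Synthetic forcing
# ---------------------------------------------------------------------------

def _daily_normal_tmean(doy: int, normals: ClimateNormals) -> float:
    """Smooth periodic interpolation of the monthly normals at mid-month."""
    mid = np.array([15.5 + 30.4375 * m for m in range(12)])
    temps = np.array(normals.monthly_tmean)
    xs = np.concatenate([mid - 365.25, mid, mid + 365.25])
    ys = np.concatenate([temps, temps, temps])
    return float(np.interp(doy, xs, ys))


def generate_weather(
    normals: ClimateNormals,
    start: dt.date,
    end: dt.date,
    seed: int,
) -> list[WeatherDay]:
    """Generate a synthetic daily forcing series for one season.

    Deterministic for a given *seed*. Daily mean temperature follows the
    interpolated monthly normals plus bounded AR(1) noise; tmin/tmax are
    built jointly around the mean so tmax >= tmin always. Rainfall is
    event-based: per-month event counts ~ Poisson with means proportional
    to the monthly fractions, depths ~ exponential, then every depth is
    rescaled so the season total equals ``normals.seasonal_rain_mm``
    exactly.
    """
    if end < start:
        raise ValueError("empty season: end before start")
    if start.year != end.year:
        raise ValueError("season must lie within one calendar year")
    rng = np.random.default_rng(seed)
    n_days = (end - start).days + 1
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]

    # temperature: normals + bounded AR(1) anomaly (zero-mean)
    anom = np.empty(n_days)
    a = 0.0
    for i in range(n_days):
        a = 0.7 * a + rng.normal(0.0, 1.4)
        anom[i] = max(-5.0, min(5.0, a))
    tmean = np.array([_daily_normal_tmean(d.timetuple().tm_yday, normals)
                      for d in dates]) + anom
    half_range = 0.5 * normals.diurnal_range \
        + rng.normal(0.0, 1.0, n_days).clip(-2.5, 2.5)
    half_range = half_range.clip(1.0, None)
    tmax = tmean + half_range
    tmin = tmean - half_range

    # rainfall: monthly Poisson event counts, exponential depths, exact rescale
    month_of = np.array([d.month for d in dates])
    rain = np.zeros(n_days)
    mean_depth = 8.0  # mm per event before rescaling
    frac = np.array(normals.monthly_rain_fraction)
    present = sorted(set(month_of))
    frac_in = frac[[m - 1 for m in present]].sum()
    for m in present:
        idx = np.flatnonzero(month_of == m)
        lam = normals.seasonal_rain_mm * frac[m - 1] / (frac_in * mean_depth)
        k = rng.poisson(lam)
        if k == 0:
            continue
        which = rng.choice(idx, size=min(k, len(idx)), replace=False)
        rain[which] += rng.exponential(mean_depth, size=len(which))
    if rain.sum() <= 0.0:
        # degenerate draw: put one event in the wettest in-season month
        m_star = max(present, key=lambda m: frac[m - 1])
        rain[rng.choice(np.flatnonzero(month_of == m_star))] = 1.0
    rain *= normals.seasonal_rain_mm / rain.sum()

    # honor the July-August concentration constraint for monsoon presets
    target_ja = frac[6] + frac[7]
    if target_ja >= 0.70 and {7, 8} <= set(present):
        ja = (month_of == 7) | (month_of == 8)
        share = rain[ja].sum() / normals.seasonal_rain_mm
        if share < 0.70:
            if rain[ja].sum() == 0.0:
                rain[np.flatnonzero(ja)[0]] = 1.0
            rain[ja] *= 0.70 * normals.seasonal_rain_mm / rain[ja].sum()
            rest = rain[~ja].sum()
            if rest > 0:
                rain[~ja] *= 0.30 * normals.seasonal_rain_mm / rest
            rain *= normals.seasonal_rain_mm / rain.sum()

    sun_frac = (normals.mean_sunshine_fraction
                + rng.normal(0.0, 0.12, n_days)).clip(0.05, 1.0)
    # rainy days are cloudier
    sun_frac = np.where(rain > 0.5, sun_frac * 0.5, sun_frac)
    rh = (normals.mean_rh + rng.normal(0.0, 8.0, n_days)).clip(5.0, 98.0)
    rh = np.where(rain > 0.5, np.minimum(rh + 25.0, 98.0), rh)
    wind = rng.gamma(4.0, normals.mean_wind / 4.0, n_days).clip(0.1, None)

    days = []
    for i, date in enumerate(dates):
        n_hours = daylength_hours(date, normals.latitude)
        days.append(WeatherDay(
            date=date,
            tmax=round(float(tmax[i]), 6),
            tmin=round(float(tmin[i]), 6),
            sunshine=round(float(sun_frac[i] * n_hours), 6),
            rh_mean=round(float(rh[i]), 6),
            wind2m=round(float(wind[i]), 6),
            rain=float(rain[i]),
        ))
    return days
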