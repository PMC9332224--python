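"""Daily meteorological forcing: validation, FAO-56 reference
evapotranspiration and growing degree days.

The reference evapotranspiration (ET0) follows the daily FAO-56
Penman-Monteith procedure for a hypothetical grass reference surface:

    ET0 = (0.408 Δ (Rn - G) + γ 900/(T+273) u2 (es - ea))
          / (Δ + γ (1 + 0.34 u2))

with the soil heat flux G taken as zero at the daily time step, actual
vapour pressure derived from mean relative humidity, and net radiation
assembled from measured shortwave radiation (albedo 0.23) and the FAO-56
Stefan-Boltzmann net-longwave term using clear-sky radiation computed
from extraterrestrial radiation at the site latitude.

Thermal time uses the clipped-average growing-degree-day method: both
daily extremes are clipped into [Tbase, Tupper] before averaging.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "SiteInfo",
    "GddParams",
    "reference_et0",
    "daily_gdd",
    "cumulative_gdd",
    "read_weather_csv",
    "DEFAULT_WIND_MS",
]

#: FAO-56 fallback wind speed for stations that do not record wind (m/s).
DEFAULT_WIND_MS = 2.0

# Stefan-Boltzmann constant, MJ K^-4 m^-2 day^-1 (FAO-56 value)
_SIGMA = 4.903e-9
# Solar constant, MJ m^-2 min^-1
_GSC = 0.0820


@dataclass(frozen=True)
class DailyWeather:
    """One day of meteorological forcing.

    Units: temperatures in deg C, relative humidity in percent (0-100),
    rainfall in mm/day, wind speed at 2 m in m/s, solar radiation in
    MJ m^-2 day^-1.
    """

    date: _dt.date
    tmin: float
    tmax: float
    rh_mean: float
    rain: float
    wind2m: float = DEFAULT_WIND_MS
    solar_rad: float = 15.0

    def __post_init__(self) -> None:
        vals = (self.tmin, self.tmax, self.rh_mean, self.rain,
                self.wind2m, self.solar_rad)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite weather value on {self.date}: {vals}")
        if self.tmin > self.tmax:
            raise ValueError(
                f"tmin ({self.tmin}) exceeds tmax ({self.tmax}) on {self.date}")
        if not 0.0 <= self.rh_mean <= 100.0:
            raise ValueError(f"rh_mean {self.rh_mean} outside [0, 100]")
        if self.rain < 0 or self.wind2m < 0 or self.solar_rad < 0:
            raise ValueError("rain, wind2m and solar_rad must be non-negative")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)

    @property
    def day_of_year(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass(frozen=True)
class SiteInfo:
    """Station latitude (decimal degrees, +N) and elevation (m a.s.l.)."""

    latitude: float = 34.467
    elevation: float = 1000.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.elevation < -430.0:
            raise ValueError(f"elevation {self.elevation} below -430 m")


@dataclass(frozen=True)
class GddParams:
    """Base and upper temperatures (deg C) bounding thermal-time accrual."""

    tbase: float = 8.0
    tupper: float = 32.0

    def __post_init__(self) -> None:
        if not self.tbase < self.tupper:
            raise ValueError("tbase must be strictly below tupper")


def _sat_vapour_pressure(t_c: float) -> float:
    """Saturation vapour pressure e0(T), kPa (FAO-56 Eq. 11 form)."""
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def extraterrestrial_radiation(latitude_deg: float, day_of_year: int) -> float:
    """Daily extraterrestrial radiation Ra, MJ m^-2 day^-1.

    Standard astronomical formula from inverse relative Earth-Sun
    distance, solar declination and sunset hour angle.
    """
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))  # polar day/night guard
    ra = (24.0 * 60.0 / math.pi) * _GSC * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))
    return max(ra, 0.0)


def reference_et0(w: DailyWeather, site: SiteInfo, day_of_year: int | None = None) -> float:
    """FAO-56 Penman-Monteith daily reference evapotranspiration, mm/day.

    Parameters
    ----------
    w
        Validated daily weather record.
    site
        Latitude and elevation of the station.
    day_of_year
        1-366; defaults to the calendar day of ``w.date``.

    Returns
    -------
    float
        ET0 >= 0 in mm/day.
    """
    if day_of_year is None:
        day_of_year = w.day_of_year
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day_of_year {day_of_year} outside [1, 366]")

    tmean = w.tmean
    # slope of the saturation vapour pressure curve, kPa/degC
    delta = 4098.0 * _sat_vapour_pressure(tmean) / (tmean + 237.3) ** 2
    # atmospheric pressure from elevation, kPa, and psychrometric constant
    pressure = 101.3 * ((293.0 - 0.0065 * site.elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    # vapour pressures, kPa
    es = 0.5 * (_sat_vapour_pressure(w.tmax) + _sat_vapour_pressure(w.tmin))
    ea = es * w.rh_mean / 100.0
    # radiation terms, MJ m^-2 day^-1
    ra = extraterrestrial_radiation(site.latitude, day_of_year)
    rso = (0.75 + 2e-5 * site.elevation) * ra
    rns = (1.0 - 0.23) * w.solar_rad
    if rso > 0:
        rel_rad = min(w.solar_rad / rso, 1.0)
    else:
        rel_rad = 1.0  # polar night: cloudiness factor indeterminate
    tmax_k4 = (w.tmax + 273.16) ** 4
    tmin_k4 = (w.tmin + 273.16) ** 4
    rnl = (_SIGMA * 0.5 * (tmax_k4 + tmin_k4)
           * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
           * (1.35 * rel_rad - 0.35))
    rn = rns - rnl
    g = 0.0  # daily step: soil heat flux negligible

    num = (0.408 * delta * (rn - g)
           + gamma * (900.0 / (tmean + 273.0)) * w.wind2m * (es - ea))
    et0 = num / (delta + gamma * (1.0 + 0.34 * w.wind2m))
    return max(et0, 0.0)


def daily_gdd(tmin: float, tmax: float, p: GddParams) -> float:
    """Growing degree days for one day, clipped-average method.

    Both extremes are clipped into [tbase, tupper] before averaging;
    the result is max(0, (tmin' + tmax')/2 - tbase).
    """
    if tmin > tmax:
        raise ValueError(f"tmin ({tmin}) exceeds tmax ({tmax})")
    lo = min(max(tmin, p.tbase), p.tupper)
    hi = min(max(tmax, p.tbase), p.tupper)
    return max(0.0, 0.5 * (lo + hi) - p.tbase)


def cumulative_gdd(series: Sequence[DailyWeather], p: GddParams) -> np.ndarray:
    """Running cumulative growing degree days over a daily series.

    Returns a nondecreasing array with one entry per day. Dates must be
    strictly increasing.
    """
    if len(series) == 0:
        raise ValueError("empty weather series")
    dates = [w.date for w in series]
    for prev, cur in zip(dates, dates[1:]):
        if cur <= prev:
            raise ValueError(f"dates not strictly increasing at {cur}")
    daily = np.array([daily_gdd(w.tmin, w.tmax, p) for w in series])
    return np.cumsum(daily)


_WEATHER_COLUMNS = {
    "date": "date",
    "tmin_c": "tmin",
    "tmax_c": "tmax",
    "rh_pct": "rh_mean",
    "rain_mm": "rain",
    "srad_mj_m2": "solar_rad",
}


def read_weather_csv(path, default_wind: float = DEFAULT_WIND_MS) -> list[DailyWeather]:
    """Read a daily weather CSV into validated records.

    Expected columns: ``date, tmin_c, tmax_c, rh_pct, rain_mm, srad_mj_m2``
    and optionally ``wind_ms`` (defaulting to the FAO-56 fallback of
    2 m/s where absent). Rows violating the physical invariants are
    rejected with the offending line number.
    """
    df = pd.read_csv(path)
    missing = set(_WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    records: list[DailyWeather] = []
    has_wind = "wind_ms" in df.columns
    for idx, row in df.iterrows():
        wind = float(row["wind_ms"]) if has_wind and pd.notna(row.get("wind_ms")) \
            else default_wind
        try:
            records.append(DailyWeather(
                date=_dt.date.fromisoformat(str(row["date"])),
                tmin=float(row["tmin_c"]),
                tmax=float(row["tmax_c"]),
                rh_mean=float(row["rh_pct"]),
                rain=float(row["rain_mm"]),
                wind2m=wind,
                solar_rad=float(row["srad_mj_m2"]),
            ))
        except (ValueError, TypeError) as exc:
            # +2: header line plus 1-based indexing
            raise ValueError(f"invalid weather row at line {idx + 2}: {exc}") from exc
    return records


def weather_to_frame(series: Iterable[DailyWeather]) -> pd.DataFrame:
    """Daily records as a DataFrame in the CSV column schema."""
    rows = [{
        "date": w.date.isoformat(),
        "tmin_c": w.tmin,
        "tmax_c": w.tmax,
        "rh_pct": w.rh_mean,
        "rain_mm": w.rain,
        "wind_ms": w.wind2m,
        "srad_mj_m2": w.solar_rad,
    } for w in series]
    return pd.DataFrame(rows)
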