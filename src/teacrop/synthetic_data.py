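"""Synthetic tea-station inputs with known ground truth.

Two generators: daily weather series whose annual means match the
study-site statistics for 2016-2019 (a mid-latitude mountain valley at
~1000 m with a July-August monsoon), and plot-level plucking records
whose yields come from the tea simulator plus per-plot multiplicative
effects and observation noise. Everything is seeded and reproducible;
a SyntheticTruth ledger records what was generated so recovery tests
can invert the process.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metforcing import DEFAULT_WIND_MS, DailyWeather, SiteInfo
from .soilwater import SoilProfile, DEFAULT_SOIL
from .teasim import (
    DEFAULT_CROP,
    KG_PER_ACRE_TO_T_HA,
    TeaCropParams,
    simulate_season,
)
from .mlbench import PlotSample

__all__ = [
    "WeatherGenSpec",
    "SyntheticTruth",
    "gen_weather_year",
    "gen_plot_samples",
    "default_weather_specs",
    "SEASON_START",
    "SEASON_END",
]

# Plucking season bounds (month, day): tea shoots at ~1000 m elevation
# flush from mid-spring to mid-autumn; outside this window the canopy is
# dormant/pruned and no harvest occurs.
SEASON_START = (4, 15)
SEASON_END = (10, 15)

# Monsoon-peaked monthly rainfall shape (fractions of the annual total,
# Jan..Dec): July-August carry roughly a third of the year's rain.
_MONTHLY_RAIN_SHAPE = np.array(
    [0.05, 0.06, 0.08, 0.07, 0.05, 0.07, 0.17, 0.16, 0.09, 0.06, 0.05, 0.09])


@dataclass(frozen=True)
class WeatherGenSpec:
    """Targets for one synthetic weather year.

    Temperature/humidity/radiation targets are annual means the
    generated series must match to within 0.1 in their units; the
    monthly rain profile lists each month's total in mm (its sum is the
    annual total).
    """

    year_label: int
    target_tmin_mean: float
    target_tmax_mean: float
    target_rh_mean: float
    monthly_rain_profile: tuple[float, ...]
    target_srad_mean: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_tmin_mean >= self.target_tmax_mean:
            raise ValueError("mean tmin target must lie below mean tmax target")
        if len(self.monthly_rain_profile) != 12:
            raise ValueError("monthly_rain_profile needs 12 entries")
        if min(self.monthly_rain_profile) < 0:
            raise ValueError("monthly rain totals must be non-negative")
        if self.target_rh_mean <= 0 or self.target_rh_mean >= 100:
            raise ValueError("target_rh_mean must be inside (0, 100)")
        if self.target_srad_mean <= 0:
            raise ValueError("target_srad_mean must be positive")


# Annual weather statistics of the four study seasons: mean tmin, mean
# tmax (degC), mean RH (%), mean monthly rainfall (mm), mean daily solar
# radiation (MJ/m^2).
STUDY_YEARS: dict[int, tuple[float, float, float, float, float]] = {
    2016: (17.4, 32.4, 28.5, 92.03, 19.06),
    2017: (16.7, 32.8, 33.8, 167.0, 19.30),
    2018: (17.0, 32.5, 32.64, 149.7, 19.22),
    2019: (16.8, 31.2, 55.2, 112.0, 19.45),
}


def default_weather_specs(seed: int = 0) -> list[WeatherGenSpec]:
    """One spec per study season, seeded deterministically from ``seed``."""
    specs = []
    for i, (year, (tn, tx, rh, rain_monthly, srad)) in enumerate(sorted(STUDY_YEARS.items())):
        annual = rain_monthly * 12.0
        profile = tuple(float(v) for v in _MONTHLY_RAIN_SHAPE * annual)
        specs.append(WeatherGenSpec(
            year_label=year,
            target_tmin_mean=tn,
            target_tmax_mean=tx,
            target_rh_mean=rh,
            monthly_rain_profile=profile,
            target_srad_mean=srad,
            seed=seed * 101 + i,
        ))
    return specs


def _season_sinusoid(doys: np.ndarray, mean: float, amplitude: float,
                     peak_doy: float) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * math.pi * (doys - peak_doy) / 365.25)


def gen_weather_year(spec: WeatherGenSpec, noise_sd: float = 1.5,
                     wind_ms: float = DEFAULT_WIND_MS) -> list[DailyWeather]:
    """Generate one calendar year of daily weather.

    Temperatures follow a seasonal sinusoid (July peak) with seeded
    Gaussian noise and a mean-correction pass so the annual means hit
    the spec targets; relative humidity peaks in the monsoon and solar
    radiation in early summer, both mean-corrected; rainfall is a
    Bernoulli occurrence / exponential intensity process rescaled so
    each month's total matches the profile exactly.
    """
    rng = np.random.default_rng(spec.seed)
    year = spec.year_label
    start = _dt.date(year, 1, 1)
    n_days = (_dt.date(year + 1, 1, 1) - start).days
    dates = [start + _dt.timedelta(days=i) for i in range(n_days)]
    doys = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    tmin = _season_sinusoid(doys, spec.target_tmin_mean, 9.0, 196.0)
    tmax = _season_sinusoid(doys, spec.target_tmax_mean, 9.0, 196.0)
    if noise_sd > 0:
        shared = rng.normal(0.0, noise_sd, n_days)  # synoptic, moves both extremes
        tmin = tmin + shared + rng.normal(0.0, 0.5 * noise_sd, n_days)
        tmax = tmax + shared + rng.normal(0.0, 0.5 * noise_sd, n_days)
    tmin += spec.target_tmin_mean - tmin.mean()
    tmax += spec.target_tmax_mean - tmax.mean()
    # the >= 14 degC mean gap makes crossings vanishingly rare; repair any
    cross = tmin > tmax
    tmin[cross] = tmax[cross]

    rh_amp = min(12.0, spec.target_rh_mean - 2.0, 98.0 - spec.target_rh_mean)
    rh = _season_sinusoid(doys, spec.target_rh_mean, rh_amp, 212.0)
    if noise_sd > 0:
        rh = rh + rng.normal(0.0, 2.0 * noise_sd, n_days)
    rh += spec.target_rh_mean - rh.mean()
    rh = np.clip(rh, 1.0, 99.0)

    srad = _season_sinusoid(doys, spec.target_srad_mean, 7.0, 172.0)
    if noise_sd > 0:
        srad = srad + rng.normal(0.0, noise_sd, n_days)
    srad += spec.target_srad_mean - srad.mean()
    srad = np.clip(srad, 0.5, None)

    rain = np.zeros(n_days)
    months = np.array([d.month for d in dates])
    for m in range(1, 13):
        idx = np.flatnonzero(months == m)
        target_total = spec.monthly_rain_profile[m - 1]
        if target_total <= 0:
            continue
        wet = rng.random(idx.size) < 0.35
        amounts = np.where(wet, rng.exponential(1.0, idx.size), 0.0)
        if amounts.sum() <= 0:  # force at least one wet day
            amounts[rng.integers(idx.size)] = 1.0
        rain[idx] = amounts * (target_total / amounts.sum())

    return [DailyWeather(date=d, tmin=float(tmin[i]), tmax=float(tmax[i]),
                         rh_mean=float(rh[i]), rain=float(rain[i]),
                         wind2m=wind_ms, solar_rad=float(srad[i]))
            for i, d in enumerate(dates)]


def season_window(weather_year: Sequence[DailyWeather]) -> list[DailyWeather]:
    """Slice a calendar year down to the plucking season."""
    year = weather_year[0].date.year
    lo = _dt.date(year, *SEASON_START)
    hi = _dt.date(year, *SEASON_END)
    return [w for w in weather_year if lo <= w.date <= hi]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for generated plot samples."""

    crop: TeaCropParams
    plot_effects: dict[str, float]
    noise_sd: float
    #: simulator seasonal yield per year, t/ha (before plot effects)
    sim_yields: dict[int, float]
    #: per (plot_id, year) seasonal yield, t/ha (after plot effect, before noise)
    seasonal_yields: dict[str, float]
    #: per (plot_id, year) observed seasonal yield, t/ha (after noise)
    observed_yields: dict[str, float]
    seed: int = 0

    def to_json(self) -> str:
        d = {
            "crop": {k: getattr(self.crop, k)
                     for k in TeaCropParams.__dataclass_fields__},
            "plot_effects": self.plot_effects,
            "noise_sd": self.noise_sd,
            "sim_yields_t_ha": {str(k): v for k, v in self.sim_yields.items()},
            "seasonal_yields_t_ha": self.seasonal_yields,
            "observed_yields_t_ha": self.observed_yields,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def gen_plot_samples(
    n_plots: int = 4,
    seasons: Sequence[WeatherGenSpec] | None = None,
    crop: TeaCropParams = DEFAULT_CROP,
    soil: SoilProfile = DEFAULT_SOIL,
    site: SiteInfo = SiteInfo(),
    plot_effect_sd: float = 0.10,
    noise_sd: float = 0.05,
    pluckings_per_season: int = 15,
    seed: int = 0,
    green_type_effect: float = 1.0,
    pluck_jitter: float = 150.0,
) -> tuple[list[PlotSample], SyntheticTruth]:
    """Generate plot-level plucking records from simulated seasons.

    For each season the simulator is run once on the plucking-season
    weather window under auto field-capacity irrigation; each plot's
    seasonal yield is the simulated yield times a lognormal plot effect
    (and, for green-tea plots, an optional type effect, 1 = none). The
    seasonal yield is split across plucking dates in proportion to the
    biomass the simulator accrued in each inter-plucking window (so the
    split follows canopy development and peaks with the monsoon flush),
    jittered by a Dirichlet draw around those shares; features are the
    weather aggregates of the window since the previous plucking, and
    multiplicative lognormal observation noise is applied before
    conversion to kg per one-acre plot.

    The defaults (4 plots x 4 seasons x 15 pluckings = 240 records)
    emulate the size of the study's plot-level dataset.
    """
    if n_plots < 1 or pluckings_per_season < 1:
        raise ValueError("need n_plots >= 1 and pluckings_per_season >= 1")
    if seasons is None:
        seasons = default_weather_specs(seed=seed)
    rng = np.random.default_rng(seed + 7919)

    plot_ids = [f"P{i + 1:02d}" for i in range(n_plots)]
    tea_types = {pid: ("green" if i % 2 == 0 else "black")
                 for i, pid in enumerate(plot_ids)}
    if plot_effect_sd > 0:
        sigma = math.sqrt(math.log(1.0 + plot_effect_sd ** 2))
        # mean-1 lognormal so effects multiply to ~1 on average
        effects = rng.lognormal(-0.5 * sigma ** 2, sigma, n_plots)
    else:
        effects = np.ones(n_plots)
    plot_effects = {pid: float(e) for pid, e in zip(plot_ids, effects)}

    samples: list[PlotSample] = []
    sim_yields: dict[int, float] = {}
    seasonal_yields: dict[str, float] = {}
    observed_yields: dict[str, float] = {}

    for spec in seasons:
        year_weather = gen_weather_year(spec)
        window = season_window(year_weather)
        result = simulate_season(window, site, crop, soil,
                                 irrigation_policy="auto_fc")
        sim_yields[spec.year_label] = result.yield_t_ha

        n = len(window)
        # plucking dates: evenly spaced through the season, last = season end
        idx = np.linspace(n / pluckings_per_season, n - 1,
                          pluckings_per_season).round().astype(int)
        pluck_dates = [window[i].date for i in idx]
        # per-window share of the season's biomass accrual
        cum_b = result.daily["biomass_t_ha"].to_numpy()
        edges = np.concatenate([[0.0], cum_b[idx]])
        increments = np.diff(edges)
        base_share = increments / increments.sum()
        # Dirichlet jitter around the mechanistic shares
        alpha = np.maximum(base_share * pluck_jitter, 1e-3)

        for pid in plot_ids:
            type_mult = green_type_effect if tea_types[pid] == "green" else 1.0
            plot_yield = result.yield_t_ha * plot_effects[pid] * type_mult
            key = f"{pid}/{spec.year_label}"
            seasonal_yields[key] = plot_yield

            weights = rng.dirichlet(alpha)
            if noise_sd > 0:
                ns = math.sqrt(math.log(1.0 + noise_sd ** 2))
                noise = rng.lognormal(-0.5 * ns ** 2, ns, pluckings_per_season)
            else:
                noise = np.ones(pluckings_per_season)

            prev = 0
            observed_total = 0.0
            for j, (i_end, d) in enumerate(zip(idx, pluck_dates)):
                win = window[prev:i_end + 1]
                prev = i_end + 1
                y_t_ha = plot_yield * weights[j] * noise[j]
                observed_total += y_t_ha
                samples.append(PlotSample(
                    plot_id=pid,
                    date=d,
                    tea_type=tea_types[pid],
                    tmin=float(np.mean([w.tmin for w in win])),
                    tmax=float(np.mean([w.tmax for w in win])),
                    rh_mean=float(np.mean([w.rh_mean for w in win])),
                    rain=float(np.sum([w.rain for w in win])),
                    yield_obs=y_t_ha / KG_PER_ACRE_TO_T_HA,
                ))
            observed_yields[key] = observed_total

    truth = SyntheticTruth(crop=crop, plot_effects=plot_effects,
                           noise_sd=noise_sd, sim_yields=sim_yields,
                           seasonal_yields=seasonal_yields,
                           observed_yields=observed_yields, seed=seed)
    return samples, truth
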