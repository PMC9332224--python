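"""Water-driven tea yield engine.

The chain is the classic water-driven crop-model cascade: canopy cover
develops from a post-pruning initial fraction towards its maximum;
transpiration is the product of evaporative demand (ET0), a canopy-
proportional transpiration coefficient and stress multipliers; biomass
accrues in proportion to normalised transpiration through the
climate-normalised water productivity WP*; and yield is the harvest-
index fraction of biomass:

    CC(t):  exponential growth to CCx/2, exponential decay to the CCx
            ceiling thereafter
    KcTr  = KcTr,x * CC*        with CC* the micro-advection adjustment
    Tr    = Ks * (KsTr,x * KcTr) * ET0          (mm/day)
    B     = WP* * sum_i Tr_i / ET0_i            (g/m^2 -> t/ha)
    Y     = HI * B,  HI = clip(multiplier * HIo, HI_min, HI_max)

Default parameters are the calibrated tea values: CCo = 20%, CCx = 95%,
CGC = 0.7 %/day, Tbase/Tupper = 8/32 degC, KcTr,x = 0.95, WP* = 18 g/m^2,
HIo = 14% within [14%, 19%], rooting depth 2 m, 12,000 plants/ha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .metforcing import DailyWeather, GddParams, SiteInfo, reference_et0
from .soilwater import (
    RootZoneState,
    SoilProfile,
    auto_irrigation,
    ks_water,
    step_water_balance,
)

__all__ = [
    "TeaCropParams",
    "SeasonResult",
    "canopy_cover",
    "cc_star",
    "kc_tr",
    "daily_transpiration",
    "normalized_biomass",
    "harvest_index",
    "simulate_season",
    "calibrate",
    "evaluate_simulation",
    "load_crop_yaml",
    "DEFAULT_CROP",
    "KG_PER_ACRE_TO_T_HA",
]

#: 1 kg/acre in t/ha (1 acre = 0.404686 ha).
KG_PER_ACRE_TO_T_HA = 0.001 / 0.404686

IrrigationPolicy = Literal["auto_fc", "none"]


@dataclass(frozen=True)
class TeaCropParams:
    """Calibrated crop constants for tea.

    cco/ccx: initial (post-pruning) and maximum canopy cover fractions;
    cgc: canopy growth coefficient per calendar day; tbase/tupper: degC
    bounds for thermal time; kctr_x: maximum transpiration coefficient
    at full canopy; wp_star: normalised biomass water productivity in
    g/m^2; hio and [hi_min, hi_max]: reference harvest index and its
    admissible range; zx/zn: max/min effective rooting depth in m;
    density: plants/ha; ks_cold: constant cold-stress multiplier
    (KsTr,x) in [0, 1], 1 meaning no cold stress.
    """

    cco: float = 0.20
    ccx: float = 0.95
    cgc: float = 0.007
    tbase: float = 8.0
    tupper: float = 32.0
    kctr_x: float = 0.95
    wp_star: float = 18.0
    hio: float = 0.14
    hi_min: float = 0.14
    hi_max: float = 0.19
    zx: float = 2.0
    zn: float = 2.0
    density: float = 12000.0
    ks_cold: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cco < self.ccx <= 1.0):
            raise ValueError(f"require 0 < cco < ccx <= 1, got {self.cco}, {self.ccx}")
        if self.cgc <= 0:
            raise ValueError("cgc must be positive")
        if not self.hi_min <= self.hio <= self.hi_max:
            raise ValueError("hio must lie within [hi_min, hi_max]")
        if not 0.0 <= self.ks_cold <= 1.0:
            raise ValueError("ks_cold must be in [0, 1]")
        if self.tbase >= self.tupper:
            raise ValueError("tbase must be below tupper")

    @property
    def gdd_params(self) -> GddParams:
        return GddParams(tbase=self.tbase, tupper=self.tupper)


DEFAULT_CROP = TeaCropParams()


def canopy_cover(t_days: float, p: TeaCropParams) -> float:
    """Canopy cover fraction t calendar days after the season start.

    Exponential growth CC = CCo * exp(CGC * t) while CC <= CCx/2, then
    exponential decay towards the ceiling CC = CCx - 0.25 (CCx^2/CCo)
    exp(-CGC * t). The two branches meet continuously at CC = CCx/2.
    Result clipped into [0, CCx].
    """
    if t_days < 0:
        raise ValueError(f"t_days must be non-negative, got {t_days}")
    half = 0.5 * p.ccx
    cc = p.cco * math.exp(p.cgc * t_days)
    if cc > half:
        cc = p.ccx - 0.25 * (p.ccx ** 2 / p.cco) * math.exp(-p.cgc * t_days)
    return min(max(cc, 0.0), p.ccx)


def cc_star(cc: float) -> float:
    """Canopy cover adjusted for micro-advective effects.

    CC* = 1.72 CC - CC^2 + 0.30 CC^3; exceeds CC on (0, 1) because air
    moving over gaps between plants enhances transpiration per unit
    cover.
    """
    if not 0.0 <= cc <= 1.0:
        raise ValueError(f"cc {cc} outside [0, 1]")
    return 1.72 * cc - cc ** 2 + 0.30 * cc ** 3


def kc_tr(cc: float, p: TeaCropParams) -> float:
    """Crop transpiration coefficient KcTr = KcTr,x * CC*(CC)."""
    return p.kctr_x * cc_star(cc)


def daily_transpiration(ks: float, p: TeaCropParams, kctr: float,
                        et0: float) -> float:
    """Daily crop transpiration Tr = Ks * (KsTr,x * KcTr) * ET0, mm/day."""
    if min(ks, kctr, et0) < 0:
        raise ValueError("ks, kctr and et0 must be non-negative")
    if ks > 1:
        raise ValueError("ks must be in [0, 1]")
    return ks * (p.ks_cold * kctr) * et0


def normalized_biomass(tr_series: Sequence[float], et0_series: Sequence[float],
                       wp_star: float) -> float:
    """Cumulative biomass B = WP* * sum(Tr_i / ET0_i), returned in t/ha.

    WP* is in g/m^2 per unit of normalised transpiration; 1 g/m^2 =
    0.01 t/ha. Days with ET0 = 0 contribute nothing provided Tr = 0 too;
    Tr > 0 with ET0 = 0 is undefined and rejected.
    """
    tr = np.asarray(tr_series, dtype=float)
    et0 = np.asarray(et0_series, dtype=float)
    if tr.shape != et0.shape:
        raise ValueError("tr and et0 series must have equal length")
    if tr.size == 0:
        return 0.0
    bad = (et0 <= 0) & (tr > 0)
    if bad.any():
        raise ValueError(
            f"transpiration positive with ET0 = 0 on day index {int(np.argmax(bad))}")
    ratio = np.where(et0 > 0, tr / np.where(et0 > 0, et0, 1.0), 0.0)
    return wp_star * float(ratio.sum()) * 0.01


def harvest_index(multiplier: float, p: TeaCropParams) -> float:
    """Harvest index HI = multiplier * HIo, clipped into [hi_min, hi_max]."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return min(max(multiplier * p.hio, p.hi_min), p.hi_max)


@dataclass
class SeasonResult:
    """Daily trajectories and seasonal totals of one simulated season."""

    daily: pd.DataFrame  # date, et0_mm, cc, kc_tr, ks, tr_mm, biomass_t_ha
    biomass_t_ha: float
    hi: float
    yield_t_ha: float


def simulate_season(
    weather: Sequence[DailyWeather],
    site: SiteInfo,
    crop: TeaCropParams,
    soil: SoilProfile,
    irrigation_policy: IrrigationPolicy = "auto_fc",
    hi_multiplier: float = 1.0,
    p_upper: float = 0.5,
    cc_override: float | None = None,
) -> SeasonResult:
    """Run one growing season day by day.

    ``cc_override`` pins the canopy at a constant fraction for the whole
    season (analytic-limit and debugging runs); by default the canopy
    follows the growth law from CCo.

    Each day: ET0 from the weather, canopy cover from the calendar-day
    clock, KcTr from the adjusted cover, the water-stress coefficient
    from post-infiltration root-zone depletion, transpiration, then the
    bucket water balance and the biomass increment. The season starts
    from the post-pruning canopy CCo with the root zone at field
    capacity. Under the ``auto_fc`` policy the profile is refilled to
    field capacity every day, so Ks = 1 throughout.
    """
    if len(weather) == 0:
        raise ValueError("empty weather series")
    rootdepth = crop.zx
    taw = soil.taw_mm(rootdepth)
    state = RootZoneState.at_field_capacity(soil, rootdepth)

    rows = []
    tr_list: list[float] = []
    et0_list: list[float] = []
    for t, w in enumerate(weather):
        try:
            et0 = reference_et0(w, site)
            cc = (cc_override if cc_override is not None
                  else canopy_cover(float(t), crop))
            kctr = kc_tr(cc, crop)

            irrigation = (auto_irrigation(state, soil, rootdepth)
                          if irrigation_policy == "auto_fc" else 0.0)
            # stress is evaluated on the root zone after today's water input
            post_in = min(state.water_mm + w.rain + irrigation,
                          soil.sat_mm(rootdepth))
            state_in = state.with_water(post_in, soil, rootdepth)
            ks = ks_water(state_in, taw, p_upper)

            tr = daily_transpiration(ks, crop, kctr, et0)
            state, fluxes = step_water_balance(
                state, soil, rootdepth, rain=w.rain, irrigation=irrigation,
                transpiration_demand=tr)
            tr_actual = fluxes.transpiration_mm
        except ValueError as exc:
            raise ValueError(f"day {t} ({w.date}): {exc}") from exc

        tr_list.append(tr_actual)
        et0_list.append(et0)
        rows.append({
            "date": w.date,
            "et0_mm": et0,
            "cc": cc,
            "kc_tr": kctr,
            "ks": ks,
            "tr_mm": tr_actual,
            "biomass_t_ha": normalized_biomass(tr_list, et0_list, crop.wp_star),
        })

    daily = pd.DataFrame(rows)
    biomass = float(daily["biomass_t_ha"].iloc[-1])
    hi = harvest_index(hi_multiplier, crop)
    return SeasonResult(daily=daily, biomass_t_ha=biomass, hi=hi,
                        yield_t_ha=hi * biomass)


def calibrate(
    observed: Sequence[tuple[str, float]],
    weather_by_season: dict[str, Sequence[DailyWeather]],
    site: SiteInfo,
    base_crop: TeaCropParams,
    soil: SoilProfile,
    free_params: Sequence[str],
    bounds: dict[str, tuple[float, float]],
    objective: Literal["mae", "mse", "rmse"] = "rmse",
    resolution: int = 7,
    grids: dict[str, Sequence[float]] | None = None,
) -> TeaCropParams:
    """Grid-search calibration of crop constants against seasonal yields.

    Parameters
    ----------
    observed
        (season label, observed yield t/ha) pairs; every label must have
        a weather series in ``weather_by_season``.
    free_params
        Subset of {"wp_star", "hio", "cgc", "cco"} to search.
    bounds
        Per-parameter (low, high); each axis is an evenly spaced grid of
        ``resolution`` points unless an explicit grid is supplied.
    objective
        Error aggregated across seasons and minimised.
    grids
        Optional explicit per-parameter grids overriding bounds/resolution.

    Ties are broken deterministically in favour of the lexicographically
    smallest parameter vector (in ``free_params`` order).
    """
    from .mlbench import mae as _mae, mse as _mse, rmse as _rmse

    allowed = {"wp_star", "hio", "cgc", "cco"}
    unknown = set(free_params) - allowed
    if unknown:
        raise ValueError(f"unsupported free parameters: {sorted(unknown)}")
    if not observed:
        raise ValueError("need at least one observed season")
    for season, _ in observed:
        if season not in weather_by_season:
            raise ValueError(f"no weather series for season {season!r}")

    axes: list[np.ndarray] = []
    for name in free_params:
        if grids and name in grids:
            axis = np.asarray(sorted(grids[name]), dtype=float)
        else:
            lo, hi = bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {name}: {(lo, hi)}")
            axis = np.linspace(lo, hi, resolution)
        if axis.size == 0:
            raise ValueError(f"empty grid for {name}")
        axes.append(axis)

    obj_fn = {"mae": _mae, "mse": _mse, "rmse": _rmse}[objective]
    y_obs = np.array([y for _, y in observed])

    best_err = math.inf
    best_vec: tuple[float, ...] | None = None
    mesh = np.meshgrid(*axes, indexing="ij") if axes else []
    candidates = (np.stack([m.ravel() for m in mesh], axis=1)
                  if axes else np.zeros((1, 0)))
    # lexicographic scan order doubles as the deterministic tie-break
    order = np.lexsort(tuple(candidates[:, i] for i in reversed(range(candidates.shape[1])))) \
        if candidates.shape[1] else np.array([0])
    for idx in order:
        vec = tuple(candidates[idx])
        crop = replace(base_crop, **dict(zip(free_params, vec)))
        try:
            sims = np.array([
                simulate_season(weather_by_season[season], site, crop, soil).yield_t_ha
                for season, _ in observed
            ])
            err = obj_fn(y_obs, sims)
        except ValueError:
            continue
        if math.isfinite(err) and err < best_err - 1e-15:
            best_err = err
            best_vec = vec
    if best_vec is None:
        raise ValueError("objective non-finite for every grid candidate")
    return replace(base_crop, **dict(zip(free_params, best_vec)))


def evaluate_simulation(observed: Sequence[float], simulated: Sequence[float]):
    """MAE/MSE/RMSE of simulated vs observed seasonal yields (t/ha)."""
    from .mlbench import EvalResult, mae, mse, rmse

    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.size == 0 or obs.shape != sim.shape:
        raise ValueError("observed and simulated must have equal nonzero length")
    return EvalResult(
        method="AquaCrop-style simulation",
        protocol="simulation",
        mae=mae(obs, sim),
        mse=mse(obs, sim),
        rmse=rmse(obs, sim),
    )


def load_crop_yaml(path) -> TeaCropParams:
    """Load crop parameters from a YAML block; unset keys use tea defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    for name in TeaCropParams.__dataclass_fields__:
        if name in cfg and cfg[name] is not None:
            kwargs[name] = float(cfg[name])
    return TeaCropParams(**kwargs)
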