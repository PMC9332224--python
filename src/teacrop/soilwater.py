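"""Root-zone soil water: hydraulic derivations and a daily bucket balance.

The root zone is a single homogeneous compartment characterised by its
volumetric water contents at saturation, field capacity and permanent
wilting point. Daily updates add rain and irrigation (capped at
saturation), extract transpiration down to the wilting point, and
percolate water standing above field capacity at a rate governed by the
dimensionless drainage coefficient tau. An auto-irrigation policy that
refills storage to field capacity each day reproduces a stress-free
regime in which the water-stress coefficient Ks is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = [
    "SoilProfile",
    "RootZoneState",
    "WaterFluxes",
    "derive_taw",
    "derive_tau",
    "auto_irrigation",
    "step_water_balance",
    "ks_water",
    "load_soil_yaml",
    "DEFAULT_SOIL",
]


def derive_taw(theta_fc: float, theta_pwp: float) -> float:
    """Total available soil water, mm per metre of soil depth.

    TAW = (theta_FC - theta_PWP) x 1000, the storage between field
    capacity and permanent wilting point.
    """
    if not theta_pwp < theta_fc:
        raise ValueError(
            f"theta_pwp ({theta_pwp}) must be below theta_fc ({theta_fc})")
    return (theta_fc - theta_pwp) * 1000.0


def derive_tau(ksat: float) -> float:
    """Drainage coefficient from saturated hydraulic conductivity.

    Pedotransfer relation tau = 0.0866 * Ksat^0.35 (Ksat in mm/day),
    clipped into (0, 1].
    """
    if not ksat > 0:
        raise ValueError(f"ksat must be positive, got {ksat}")
    return min(0.0866 * ksat ** 0.35, 1.0)


@dataclass(frozen=True)
class SoilProfile:
    """Static hydraulic description of a homogeneous soil profile.

    theta_* are volumetric fractions; depth in m; ksat in mm/day; tau is
    the dimensionless daily drainage coefficient (derived from ksat if
    not given).
    """

    theta_sat: float = 0.50
    theta_fc: float = 0.39
    theta_pwp: float = 0.23
    depth_m: float = 2.0
    ksat: float = 500.0
    tau: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_pwp < self.theta_fc < self.theta_sat <= 1.0):
            raise ValueError(
                "require 0 < theta_pwp < theta_fc < theta_sat <= 1, got "
                f"{self.theta_pwp}, {self.theta_fc}, {self.theta_sat}")
        if self.depth_m <= 0:
            raise ValueError("depth_m must be positive")
        if self.ksat <= 0:
            raise ValueError("ksat must be positive")
        if self.tau is None:
            object.__setattr__(self, "tau", derive_tau(self.ksat))
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau {self.tau} outside (0, 1]")

    # storage depths over a given rooting depth, mm
    def sat_mm(self, rootdepth_m: float) -> float:
        return self.theta_sat * rootdepth_m * 1000.0

    def fc_mm(self, rootdepth_m: float) -> float:
        return self.theta_fc * rootdepth_m * 1000.0

    def pwp_mm(self, rootdepth_m: float) -> float:
        return self.theta_pwp * rootdepth_m * 1000.0

    def taw_mm(self, rootdepth_m: float) -> float:
        return derive_taw(self.theta_fc, self.theta_pwp) * rootdepth_m


DEFAULT_SOIL = SoilProfile()


@dataclass(frozen=True)
class RootZoneState:
    """Evolving water store of the root zone (depths in mm).

    ``depletion_mm`` is the shortfall below field-capacity storage and is
    recomputable from ``water_mm``; it is carried for convenience.
    """

    water_mm: float
    depletion_mm: float = 0.0

    @staticmethod
    def at_field_capacity(profile: SoilProfile, rootdepth_m: float) -> "RootZoneState":
        return RootZoneState(water_mm=profile.fc_mm(rootdepth_m), depletion_mm=0.0)

    def with_water(self, water_mm: float, profile: SoilProfile,
                   rootdepth_m: float) -> "RootZoneState":
        return RootZoneState(
            water_mm=water_mm,
            depletion_mm=max(0.0, profile.fc_mm(rootdepth_m) - water_mm),
        )


@dataclass(frozen=True)
class WaterFluxes:
    """Daily water-balance ledger, all entries in mm/day, non-negative."""

    infiltration_mm: float = 0.0
    drainage_mm: float = 0.0
    transpiration_mm: float = 0.0
    irrigation_mm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("infiltration_mm", "drainage_mm",
                     "transpiration_mm", "irrigation_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def auto_irrigation(state: RootZoneState, profile: SoilProfile,
                    rootdepth_m: float) -> float:
    """Irrigation depth (mm) restoring storage exactly to field capacity.

    Returns 0 when the profile is at or above field capacity.
    """
    return max(0.0, profile.fc_mm(rootdepth_m) - state.water_mm)


def step_water_balance(
    state: RootZoneState,
    profile: SoilProfile,
    rootdepth_m: float,
    rain: float,
    irrigation: float,
    transpiration_demand: float,
) -> tuple[RootZoneState, WaterFluxes]:
    """Advance the root-zone bucket by one day.

    Order of operations: (1) rain + irrigation infiltrate, capped at
    saturation with the excess shed as same-day drainage; (2) the
    transpiration demand is extracted, limited by water standing above
    the wilting point; (3) water above field capacity percolates at rate
    tau * (storage - FC storage). Mass balance closes exactly:
    new = old + infiltration + irrigation - transpiration - drainage.
    """
    if rain < 0 or irrigation < 0 or transpiration_demand < 0:
        raise ValueError("fluxes must be non-negative")

    sat = profile.sat_mm(rootdepth_m)
    fc = profile.fc_mm(rootdepth_m)
    pwp = profile.pwp_mm(rootdepth_m)

    water = state.water_mm
    # infiltration capped at saturation; surplus leaves as drainage
    room = max(0.0, sat - water)
    supply = rain + irrigation
    entered = min(supply, room)
    drainage = supply - entered
    water += entered
    # rain fills first; irrigation tops up (split is bookkeeping only)
    infiltration = min(rain, entered)
    irrigation_in = entered - infiltration

    # transpiration limited by extractable water above wilting point
    transpiration = min(transpiration_demand, max(0.0, water - pwp))
    water -= transpiration

    # deep percolation of above-FC water
    if water > fc:
        perc = profile.tau * (water - fc)
        water -= perc
        drainage += perc

    new_state = RootZoneState(water_mm=water,
                              depletion_mm=max(0.0, fc - water))
    fluxes = WaterFluxes(
        infiltration_mm=infiltration,
        drainage_mm=drainage,
        transpiration_mm=transpiration,
        irrigation_mm=irrigation_in,
    )
    return new_state, fluxes


def ks_water(state: RootZoneState, taw_mm: float, p_upper: float = 0.5) -> float:
    """Water-stress coefficient Ks in [0, 1].

    Ks = 1 while root-zone depletion stays at or below p_upper * TAW
    (no stomatal closure), then declines linearly to 0 at full depletion
    (wilting point).
    """
    if taw_mm <= 0:
        raise ValueError("taw_mm must be positive")
    if not 0.0 <= p_upper < 1.0:
        raise ValueError(f"p_upper {p_upper} outside [0, 1)")
    d = state.depletion_mm
    threshold = p_upper * taw_mm
    if d <= threshold:
        return 1.0
    if d >= taw_mm:
        return 0.0
    return (taw_mm - d) / (taw_mm - threshold)


def load_soil_yaml(path) -> SoilProfile:
    """Load a soil profile from a YAML block.

    Keys: ``theta_sat, theta_fc, theta_pwp, depth_m, ksat_mm_day`` and
    optional ``tau`` (derived from ksat when absent).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return SoilProfile(
        theta_sat=float(cfg.get("theta_sat", DEFAULT_SOIL.theta_sat)),
        theta_fc=float(cfg.get("theta_fc", DEFAULT_SOIL.theta_fc)),
        theta_pwp=float(cfg.get("theta_pwp", DEFAULT_SOIL.theta_pwp)),
        depth_m=float(cfg.get("depth_m", DEFAULT_SOIL.depth_m)),
        ksat=float(cfg.get("ksat_mm_day", DEFAULT_SOIL.ksat)),
        tau=(float(cfg["tau"]) if "tau" in cfg and cfg["tau"] is not None else None),
    )
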