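"""Actual-evapotranspiration module.

Potential crop ET is scaled from reference ET0 by a canopy coefficient
driven by leaf area index, split into potential soil evaporation and
transpiration by Beer's-law light interception, and each component is then
reduced linearly by moisture availability.
"""

from __future__ import annotations

from dataclasses import dataclass

from awpm.soil import SoilHydraulicParams

__all__ = [
    "ETCoefficients", "ETDemand", "potential_et", "partition",
    "actual_soil_evap", "actual_transpiration",
]


@dataclass(frozen=True)
class ETCoefficients:
    """Tunable coefficients of the ET module.

    kc_mx: crop coefficient at full canopy; lai_ref: LAI at which the
    coefficient saturates; k_beer: canopy extinction coefficient; p:
    depletion fraction placing the critical moisture between wilting point
    and field capacity.
    """

    kc_mx: float = 1.2
    lai_ref: float = 3.0
    k_beer: float = 0.5
    p: float = 0.5


DEFAULT_ET = ETCoefficients()


@dataclass(frozen=True)
class ETDemand:
    """Potential ET split into soil-evaporation and transpiration demand."""

    pet: float
    ep: float
    tp: float

    def __post_init__(self) -> None:
        if min(self.pet, self.ep, self.tp) < 0.0:
            raise ValueError("ET components must be non-negative")
        if abs(self.ep + self.tp - self.pet) > 1e-12:
            raise ValueError("ep + tp must equal pet")


def potential_et(et0: float, lai: float,
                 coeffs: ETCoefficients = DEFAULT_ET) -> float:
    """Potential crop ET (mm d-1): et0 scaled by an LAI-driven coefficient.

    kc rises linearly from 1 at bare soil to kc_mx at lai >= lai_ref.
    """
    if et0 < 0.0 or lai < 0.0:
        raise ValueError("et0 and lai must be non-negative")
    kc = 1.0 + (coeffs.kc_mx - 1.0) * min(lai / coeffs.lai_ref, 1.0)
    return et0 * kc


def partition(pet: float, lai: float,
              coeffs: ETCoefficients = DEFAULT_ET) -> ETDemand:
    """Split potential ET by Beer's-law interception of the canopy."""
    if pet < 0.0 or lai < 0.0:
        raise ValueError("pet and lai must be non-negative")
    import math
    tp = pet * (1.0 - math.exp(-coeffs.k_beer * lai))
    return ETDemand(pet=pet, ep=pet - tp, tp=tp)


def actual_soil_evap(ep: float, theta1: float,
                     soil: SoilHydraulicParams) -> float:
    """Actual soil evaporation: linear ramp from air-dry to field capacity."""
    if ep < 0.0:
        raise ValueError("ep must be non-negative")
    frac = (theta1 - soil.md) / (soil.mfc - soil.md)
    return ep * min(1.0, max(0.0, frac))


def actual_transpiration(tp: float, theta_rz: float,
                         soil: SoilHydraulicParams,
                         coeffs: ETCoefficients = DEFAULT_ET,
                         ) -> tuple[float, float]:
    """Actual transpiration and the water-stress factor ws in [0, 1].

    ws ramps linearly from 0 at wilting point to 1 at the critical
    moisture theta_crit = mwp + p (mfc - mwp); T = ws * tp. ws is also the
    stress multiplier handed to the crop module.
    """
    if tp < 0.0:
        raise ValueError("tp must be non-negative")
    theta_crit = soil.mwp + coeffs.p * (soil.mfc - soil.mwp)
    ws = (theta_rz - soil.mwp) / (theta_crit - soil.mwp)
    ws = min(1.0, max(0.0, ws))
    return ws * tp, ws
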