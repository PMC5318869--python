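"""EPIC-style crop growth: heat units, LAI, biomass, roots, yield.

Phenology advances on accumulated heat units; leaf area follows a logistic
heat-unit factor during canopy build-up and a power-law decline after the
onset of senescence; biomass accrues from intercepted photosynthetically
active radiation at a fixed radiation-use efficiency, reduced by the more
limiting of water and temperature stress; yield is harvest index times
biomass with a penalty for stress during the reproductive window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)

__all__ = [
    "CropParams", "CropState", "MAIZE", "heat_units", "huf_shape_constants",
    "heat_unit_factor", "lai_update", "lai_after_increment",
    "biomass_increment", "root_depth", "harvest", "advance",
    "REPRODUCTIVE_WINDOW",
]

#: Heat-unit-index window over which water stress depresses the harvest index.
REPRODUCTIVE_WINDOW = (0.45, 0.80)

#: Seeding depth of influence (cm) and the root-growth speed-up factor.
ROOT_DEPTH_INITIAL = 10.0
ROOT_GROWTH_FACTOR = 2.5


def huf_shape_constants(h1: float = 0.15, f1: float = 0.05,
                        h2: float = 0.50, f2: float = 0.95,
                        ) -> tuple[float, float]:
    """Fit (l1, l2) of huf(h) = h / (h + exp(l1 - l2 h)) through two points."""
    g1 = math.log(h1 * (1.0 - f1) / f1)
    g2 = math.log(h2 * (1.0 - f2) / f2)
    l2 = (g1 - g2) / (h2 - h1)
    l1 = g1 + h1 * l2
    return l1, l2


_L1_DEFAULT, _L2_DEFAULT = huf_shape_constants()


@dataclass(frozen=True)
class CropParams:
    """EPIC-style crop parameter block.

    tb/t0: base and optimal temperature (degC); phu: potential heat units
    (degC d) to maturity; lai_mx: maximum leaf area index; dlai: heat-unit
    fraction at the onset of LAI decline; ad: decline exponent; be:
    radiation-use efficiency (kg ha-1 per MJ m-2); hi: potential harvest
    index; rd_mx: maximum rooting depth (cm); l1/l2: LAI-curve shape
    constants.
    """

    tb: float = 8.0
    t0: float = 25.0
    phu: float = 1700.0
    lai_mx: float = 6.0
    dlai: float = 0.8
    ad: float = 1.0
    be: float = 28.0
    hi: float = 0.5
    rd_mx: float = 90.0
    l1: float = _L1_DEFAULT
    l2: float = _L2_DEFAULT

    def __post_init__(self) -> None:
        if self.tb >= self.t0:
            raise ValueError("require tb < t0")
        if not 0.0 < self.dlai < 1.0:
            raise ValueError("require 0 < dlai < 1")
        if self.lai_mx <= 0 or self.phu <= 0 or self.rd_mx <= 0:
            raise ValueError("lai_mx, phu, rd_mx must be positive")
        if not 0.0 < self.hi < 1.0:
            raise ValueError("require 0 < hi < 1")


#: Recommended-default maize parameter set (starting point for calibration).
MAIZE = CropParams()


@dataclass(frozen=True)
class CropState:
    """Daily crop state: phenology, canopy, biomass, roots.

    ``lai_peak`` records the LAI at the onset of decline; ``ws_sum`` /
    ``ws_days`` accumulate water stress over the reproductive window for
    the harvest-index penalty.
    """

    hui: float = 0.0
    lai: float = 0.0
    biomass: float = 0.0
    rd: float = ROOT_DEPTH_INITIAL
    lai_peak: float = 0.0
    ws_sum: float = 0.0
    ws_days: int = 0
    yield_t_ha: float | None = None


def heat_units(tmax: float, tmin: float, crop: CropParams) -> float:
    """Degree-days above the base temperature for one day."""
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    return max(0.0, 0.5 * (tmax + tmin) - crop.tb)


def heat_unit_factor(hui: float, crop: CropParams) -> float:
    """Logistic canopy-development factor, ~0 at emergence, ~1 at hui=dlai."""
    if hui <= 0.0:
        return 0.0
    return hui / (hui + math.exp(crop.l1 - crop.l2 * hui))


def lai_update(state: CropState, ws: float, crop: CropParams,
               hui_new: float) -> tuple[float, float]:
    """Advance LAI from the state's hui to *hui_new*; return (lai, lai_peak).

    Build-up phase (hui <= dlai): the potential curve is lai_mx * huf(hui)
    and each day's potential increment is scaled by sqrt(ws). Decline
    phase: power-law fall from the peak, lai_peak ((1-hui)/(1-dlai))^ad,
    floored at zero.
    """
    return lai_after_increment(state.lai, state.hui, hui_new, ws, crop,
                               state.lai_peak)


def lai_after_increment(lai: float, hui_prev: float, hui: float, ws: float,
                        crop: CropParams, lai_peak: float) -> tuple[float, float]:
    """Advance LAI across one heat-unit increment; return (lai, lai_peak)."""
    if not 0.0 <= ws <= 1.0:
        raise ValueError("ws must lie in [0, 1]")
    if hui < hui_prev:
        raise ValueError("hui must be non-decreasing")
    if hui <= crop.dlai:
        d_pot = crop.lai_mx * (heat_unit_factor(hui, crop)
                               - heat_unit_factor(hui_prev, crop))
        lai = lai + d_pot * math.sqrt(ws)
        return lai, lai
    # crossing into or inside the decline phase
    if hui_prev <= crop.dlai:
        d_pot = crop.lai_mx * (heat_unit_factor(crop.dlai, crop)
                               - heat_unit_factor(hui_prev, crop))
        lai = lai + d_pot * math.sqrt(ws)
        lai_peak = lai
    frac = max(0.0, (1.0 - min(hui, 1.0)) / (1.0 - crop.dlai))
    return lai_peak * frac ** crop.ad, lai_peak


def biomass_increment(solar: float, lai: float, ws: float, tday: float,
                      crop: CropParams) -> float:
    """Daily above-ground biomass gain (t ha-1 d-1).

    Intercepted PAR = 0.5 solar (1 - exp(-0.65 lai)); temperature stress
    ts = sin(pi/2 * (tday - tb)/(t0 - tb)) clipped to [0, 1]; the gain is
    0.001 be PAR min(ws, ts), the 0.001 converting kg ha-1 to t ha-1.
    """
    if solar < 0.0 or lai < 0.0:
        raise ValueError("solar and lai must be non-negative")
    if not 0.0 <= ws <= 1.0:
        raise ValueError("ws must lie in [0, 1]")
    par = 0.5 * solar * (1.0 - math.exp(-0.65 * lai))
    frac = min(1.0, max(0.0, (tday - crop.tb) / (crop.t0 - crop.tb)))
    ts = math.sin(0.5 * math.pi * frac)
    return 0.001 * crop.be * par * min(ws, ts)


def root_depth(hui: float, crop: CropParams) -> float:
    """Rooting depth (cm): linear in hui, reaching rd_mx at hui = 0.4."""
    if hui < 0.0:
        raise ValueError("hui must be non-negative")
    frac = min(ROOT_GROWTH_FACTOR * hui, 1.0)
    return min(crop.rd_mx,
               ROOT_DEPTH_INITIAL + (crop.rd_mx - ROOT_DEPTH_INITIAL) * frac)


def harvest(state: CropState, crop: CropParams,
            mean_ws_reproductive: float | None = None) -> float:
    """Grain yield (t ha-1) at the end of the season.

    yield = biomass * hi * (0.5 + 0.5 * mean reproductive-window water
    stress); an unstressed season therefore yields hi * biomass. When the
    window was never entered the accumulated mean defaults to 1. Harvest
    before hui 0.5 is flagged and the harvest index scaled down
    proportionally.
    """
    if mean_ws_reproductive is None:
        mean_ws_reproductive = (state.ws_sum / state.ws_days
                                if state.ws_days > 0 else 1.0)
    if not 0.0 <= mean_ws_reproductive <= 1.0:
        raise ValueError("mean reproductive water stress must lie in [0, 1]")
    hi = crop.hi
    if state.hui < 0.5:
        logger.warning("harvest at hui=%.2f (<0.5): harvest index scaled",
                       state.hui)
        hi *= state.hui / 0.5
    return state.biomass * hi * (0.5 + 0.5 * mean_ws_reproductive)


def advance(state: CropState, tmax: float, tmin: float, solar: float,
            ws: float, crop: CropParams) -> CropState:
    """One day of crop development under today's weather and water stress."""
    hu = heat_units(tmax, tmin, crop)
    hui = state.hui + hu / crop.phu
    lai, lai_peak = lai_after_increment(state.lai, state.hui, hui, ws, crop,
                                        state.lai_peak)
    db = biomass_increment(solar, state.lai, ws, 0.5 * (tmax + tmin), crop)
    rd = max(state.rd, root_depth(hui, crop))
    lo, hi = REPRODUCTIVE_WINDOW
    in_window = lo <= hui <= hi
    return replace(
        state,
        hui=hui,
        lai=lai,
        lai_peak=lai_peak,
        biomass=state.biomass + db,
        rd=rd,
        ws_sum=state.ws_sum + (ws if in_window else 0.0),
        ws_days=state.ws_days + (1 if in_window else 0),
    )
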