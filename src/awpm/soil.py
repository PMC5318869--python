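"""Four-zone soil water balance with a dynamic shallow water table.

The profile is split into the actual root zone (zone 1, depth ``rd``), the
remaining potential root zone (zone 2, down to ``rd_mx``), a transmission
zone with no storage dynamics, and the saturated zone below the water
table. Percolation out of the rooted column follows Thornthwaite-Mather
bookkeeping; upward capillary supply is bounded by the Gardner analytical
steady-state flux for the conductivity family K(h) = ks / (1 + (alpha h)^C).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "SoilHydraulicParams", "SoilProfileState", "DailyFlux", "LOAM",
    "gardner_shape_constant", "gardner_max_flux", "capillary_rise",
    "tm_step", "update_water_table", "grow_root_zone",
]


@dataclass(frozen=True)
class SoilHydraulicParams:
    """Hydraulic parameter set for the (homogeneous) rooted column.

    Moistures are volumetric (cm3 cm-3) and must satisfy
    md < mwp < mfc < ms. ``mf`` is the drainable porosity (specific yield)
    governing water-table response; ``ks`` (cm d-1), ``alpha`` (cm-1) and
    the exponent ``C`` parameterize the Gardner conductivity function;
    ``dp`` is the fraction of percolation lost below the simulated column.
    """

    ms: float
    mfc: float
    mwp: float
    md: float
    mf: float
    ks: float
    alpha: float
    C: float
    dp: float = 0.0

    def __post_init__(self) -> None:
        if not (self.md < self.mwp < self.mfc < self.ms):
            raise ValueError("require md < mwp < mfc < ms")
        if not (0.0 < self.mf < self.ms):
            raise ValueError("require 0 < mf < ms")
        if self.ks <= 0 or self.alpha <= 0:
            raise ValueError("ks and alpha must be positive")
        if self.C <= 1.0:
            raise ValueError("conductivity exponent C must exceed 1")
        if not 0.0 <= self.dp <= 1.0:
            raise ValueError("dp must lie in [0, 1]")


#: Default loam set for the rooted column (to be calibrated per site).
LOAM = SoilHydraulicParams(
    ms=0.46, mfc=0.33, mwp=0.13, md=0.05,
    mf=0.15, ks=25.0, alpha=0.04, C=3.0, dp=0.0,
)


@dataclass(frozen=True)
class SoilProfileState:
    """Moisture state of the rooted column plus the water-table position.

    ``rd``/``rd_mx`` in cm; ``theta1``/``theta2`` are the mean volumetric
    moistures of zones 1 and 2; ``apwl`` is the accumulated potential
    water loss of the Thornthwaite-Mather ledger (mm); ``gwd`` is depth to
    the water table below the surface (cm, positive down).
    """

    rd: float
    rd_mx: float
    theta1: float
    theta2: float
    apwl: float
    gwd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rd <= self.rd_mx:
            raise ValueError("require 0 < rd <= rd_mx")
        if self.gwd <= 0.0:
            raise ValueError("water table depth must be positive")
        if self.apwl < 0.0:
            raise ValueError("apwl must be non-negative")

    @property
    def storage_mm(self) -> float:
        """Water stored in the zone-1+2 column, mm."""
        return 10.0 * (self.theta1 * self.rd
                       + self.theta2 * (self.rd_mx - self.rd))


@dataclass(frozen=True)
class DailyFlux:
    """Closed water-balance ledger for one day (all terms mm d-1).

    ``d_storage`` is the change of the rooted column's storage and
    satisfies rain + irrigation + capillary - soil_evap - transpiration -
    percolation = d_storage. ``d_gwd`` is the water-table movement in
    cm d-1 (positive = deepening).
    """

    rain: float
    irrigation: float
    soil_evap: float
    transpiration: float
    percolation: float
    capillary: float
    deep_loss: float
    d_storage: float
    d_gwd: float

    @property
    def closure_residual(self) -> float:
        return (self.rain + self.irrigation + self.capillary
                - self.soil_evap - self.transpiration - self.percolation
                - self.d_storage)


# ---------------------------------------------------------------------------
# Gardner capillary rise
# ---------------------------------------------------------------------------

def gardner_shape_constant(C: float) -> float:
    """Gardner's shape constant A for the exponent C.

    A = [pi / (C sin(pi/C))]^C; this closed form reproduces the tabulated
    values 2.46, 1.76 and 1.52 at C = 2, 3, 4.
    """
    if C <= 1.0:
        raise ValueError("C must exceed 1")
    return (math.pi / (C * math.sin(math.pi / C))) ** C


def gardner_max_flux(depth_gap: float, soil: SoilHydraulicParams) -> float:
    """Maximum steady upward flux (mm d-1) across *depth_gap* cm.

    Solves the Gardner steady-state relation for K(h)=ks/(1+(alpha h)^C):
    with q~ = q/ks, q~ (1 + q~)^(C-1) = A / (alpha d)^C, which reduces to
    the familiar q = A ks / (alpha d)^C in the deep-table limit. The result
    is clamped to [0, ks].
    """
    if not (math.isfinite(depth_gap) and depth_gap >= 0.0):
        raise ValueError("depth_gap must be finite and non-negative")
    if depth_gap == 0.0:
        return soil.ks * 10.0
    A = gardner_shape_constant(soil.C)
    rhs = A / (soil.alpha * depth_gap) ** soil.C
    # q~ (1+q~)^(C-1) is increasing in q~; q~ >= 1 already means clamp
    if rhs >= 2.0 ** (soil.C - 1.0):
        return soil.ks * 10.0
    qt = brentq(lambda q: q * (1.0 + q) ** (soil.C - 1.0) - rhs,
                0.0, 1.0, xtol=1e-15)
    return min(qt, 1.0) * soil.ks * 10.0  # cm d-1 -> mm d-1


def capillary_rise(state: SoilProfileState, soil: SoilHydraulicParams,
                   demand: float) -> float:
    """Upward flux (mm d-1) delivered to the rooted column today.

    *demand* is the unmet field-capacity deficit being refilled (zone-2
    deficit plus unmet ET). Supply is bounded by the Gardner maximum for
    the gap between the bottom of the potential root zone and the water
    table; no rise occurs once zone 2 is at field capacity.
    """
    if demand < 0.0:
        raise ValueError("demand must be non-negative")
    if state.theta2 >= soil.mfc or demand == 0.0:
        return 0.0
    gap = max(0.0, state.gwd - state.rd_mx)
    return min(demand, gardner_max_flux(gap, soil))


# ---------------------------------------------------------------------------
# Thornthwaite-Mather bookkeeping
# ---------------------------------------------------------------------------

def _rescale_moisture(state: SoilProfileState, soil: SoilHydraulicParams,
                      new_storage: float) -> SoilProfileState:
    """Back-compute zone moistures proportionally for a new column storage."""
    old = state.storage_mm
    if old <= 0.0:
        theta = new_storage / (10.0 * state.rd_mx)
        return replace(state, theta1=theta, theta2=theta)
    f = new_storage / old
    theta1 = min(state.theta1 * f, soil.ms)
    # zone 2 has zero thickness once roots fill the potential root zone;
    # keep its moisture tied to zone 1 so the capillary gate stays sane
    theta2 = theta1 if state.rd >= state.rd_mx else min(state.theta2 * f, soil.ms)
    return replace(state, theta1=theta1, theta2=theta2)


def tm_step(state: SoilProfileState, soil: SoilHydraulicParams,
            infiltration: float, et_withdrawal: float,
) -> tuple[SoilProfileState, float]:
    """One day of Thornthwaite-Mather storage accounting.

    The zone-1+2 column holds at most S_fc = mfc * rd_mx * 10 mm against
    gravity. On wetting days storage rises by the net input and any excess
    over S_fc percolates out the same day; the accumulated potential water
    loss (apwl) is reset to the value consistent with the new storage. On
    drying days apwl grows by the shortfall and storage follows
    S = S_fc exp(-apwl / S_fc).

    Returns the updated state and the percolation (mm) leaving the column.
    """
    if infiltration < 0.0 or et_withdrawal < 0.0:
        raise ValueError("fluxes must be non-negative")
    s_fc = 10.0 * soil.mfc * state.rd_mx
    s = state.storage_mm
    net = infiltration - et_withdrawal
    if net >= 0.0:
        s_new = s + net
        percolation = max(0.0, s_new - s_fc)
        s_new = min(s_new, s_fc)
        apwl = 0.0 if s_new >= s_fc else -s_fc * math.log(s_new / s_fc)
    else:
        percolation = 0.0
        # keep the ledger consistent with the actual storage before drying
        apwl0 = 0.0 if s >= s_fc else -s_fc * math.log(max(s, 1e-12) / s_fc)
        apwl = apwl0 - net
        s_new = s_fc * math.exp(-apwl / s_fc)
        floor = 10.0 * soil.md * state.rd_mx
        if s_new < floor:
            # clip at the air-dry floor but never create water
            clipped = min(floor, s + infiltration)
            logger.warning("storage %.3f mm clipped at air-dry floor "
                           "(%.3f mm)", s_new, clipped)
            s_new = clipped
            apwl = -s_fc * math.log(max(s_new, 1e-12) / s_fc)
    new_state = _rescale_moisture(state, soil, s_new)
    return replace(new_state, apwl=apwl), percolation


def update_water_table(state: SoilProfileState, soil: SoilHydraulicParams,
                       recharge: float, upflux: float) -> float:
    """New water-table depth (cm) after today's exchange with the column.

    Recharge (percolation reaching the saturated zone, less the deep-loss
    fraction dp) raises the table; capillary upflux lowers it, both scaled
    by the specific yield: d(gwd) = (upflux - (1-dp) recharge) / (10 mf).
    The table is floored at the bottom of the potential root zone.
    """
    if recharge < 0.0 or upflux < 0.0:
        raise ValueError("fluxes must be non-negative")
    if soil.mf <= 0.0:
        raise ValueError("specific yield must be positive")
    d_gwd = (upflux - (1.0 - soil.dp) * recharge) / (10.0 * soil.mf)
    gwd = state.gwd + d_gwd
    if gwd < state.rd_mx:
        logger.info("water table capped at rd_mx (%.0f cm); excess stored "
                    "saturation ignored", state.rd_mx)
        gwd = state.rd_mx
    return gwd


def grow_root_zone(state: SoilProfileState, new_rd: float) -> SoilProfileState:
    """Deepen zone 1 to *new_rd*, annexing the corresponding zone-2 slab.

    Zone 1 inherits the moisture of the annexed slab as a depth-weighted
    mean; total stored water is conserved exactly.
    """
    if new_rd < state.rd:
        raise ValueError("root zone cannot shrink")
    if new_rd > state.rd_mx:
        raise ValueError("root zone cannot exceed rd_mx")
    if new_rd == state.rd:
        return state
    annexed = new_rd - state.rd
    theta1 = (state.theta1 * state.rd + state.theta2 * annexed) / new_rd
    theta2 = theta1 if new_rd >= state.rd_mx else state.theta2
    return replace(state, rd=new_rd, theta1=theta1, theta2=theta2)
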