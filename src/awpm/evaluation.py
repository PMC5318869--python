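"""Goodness-of-fit statistics, parameter sensitivity and d-factor uncertainty."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FitStats", "UncertaintyResult", "fit_stats", "SENSITIVITY_INDEXES",
    "sensitivity_scan", "d_factor",
]


@dataclass(frozen=True)
class FitStats:
    """Standard fit statistics between a predicted and an observed series.

    mre: mean of observation-wise relative errors, %; rmse in the units of
    the series; nse: Nash-Sutcliffe efficiency; r2: squared Pearson
    correlation; b: slope of the regression through the origin. mre is NaN
    when any observation is zero; nse and r2 are NaN for constant
    observations (where they are undefined and known to mislead).
    """

    mre: float
    rmse: float
    nse: float
    r2: float
    b: float


def fit_stats(pred: Sequence[float], obs: Sequence[float]) -> FitStats:
    """Compute MRE, RMSE, NSE, R2 and the origin-regression coefficient b."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1-D series")
    if p.size < 2:
        raise ValueError("need at least two points")

    err = p - o
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mre = float(100.0 * np.mean(err / o)) if np.all(o != 0) else math.nan

    sso = float(np.sum((o - o.mean()) ** 2))
    if sso > 0:
        nse = float(1.0 - np.sum(err ** 2) / sso)
    else:
        nse = math.nan
    if o.std() > 0 and p.std() > 0:
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    elif o.std() == 0 and p.std() == 0 and np.allclose(p, o):
        r2 = 1.0
    else:
        r2 = math.nan
    b = float(np.sum(p * o) / np.sum(o ** 2)) if np.any(o != 0) else math.nan
    return FitStats(mre=mre, rmse=rmse, nse=nse, r2=r2, b=b)


# ---------------------------------------------------------------------------
# One-at-a-time sensitivity
# ---------------------------------------------------------------------------

def _index_et(result) -> float:
    return result.et_total


def _index_gwd(result) -> float:
    return float(result.daily["gwd"].mean())


def _index_lai(result) -> float:
    return float(result.daily["lai"].max())


def _index_sw90(result) -> float:
    return float(result.daily["storage"].mean())


#: Response indexes: seasonal ET (mm), mean water-table depth (cm), peak
#: LAI, and mean stored water in the top rooted column (mm).
SENSITIVITY_INDEXES = {
    "ET": _index_et,
    "GWD": _index_gwd,
    "LAI": _index_lai,
    "SW90": _index_sw90,
}

DEFAULT_DELTAS = tuple(d / 100.0 for d in range(-25, 26, 5))


def sensitivity_scan(base_config, parameter: str,
                     deltas: Sequence[float] = DEFAULT_DELTAS,
                     index: str = "ET") -> pd.DataFrame:
    """Relative response of an output index to fractional parameter changes.

    Reruns the season with the named soil/crop/et parameter scaled by
    (1 + delta) for each delta and reports (I(delta) - I(0)) / I(0).
    *base_config* is a :class:`awpm.config.RunConfig`.
    """
    from awpm.simulator import run_season

    if index not in SENSITIVITY_INDEXES:
        raise KeyError(f"unknown index {index!r}; "
                       f"choose from {sorted(SENSITIVITY_INDEXES)}")
    extract = SENSITIVITY_INDEXES[index]
    base_value = base_config.get_param(parameter)

    def run_with(value):
        cfg = base_config.with_param(parameter, value)
        return run_season(cfg.scenario, cfg.soil, cfg.crop, cfg.site, cfg.et)

    i0 = extract(run_with(base_value))
    rows = []
    for delta in deltas:
        iv = i0 if delta == 0.0 else extract(run_with(base_value * (1.0 + delta)))
        rows.append({"parameter": parameter, "delta": delta, "index": index,
                     "value": iv,
                     "rel_change": (iv - i0) / i0 if i0 != 0 else math.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# d-factor uncertainty
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertaintyResult:
    """Ensemble prediction-band width relative to observed variability."""

    d_bar: float
    sigma_x: float
    d_factor: float


def d_factor(ensemble, obs: Sequence[float],
             level: float = 0.95) -> UncertaintyResult:
    """Average width of the central *level* prediction band over sigma(obs).

    *ensemble* is (n_members, n_times); per time point the empirical
    (1 +/- level)/2 quantiles (linear interpolation of order statistics)
    bound the band.
    """
    ens = np.asarray(ensemble, dtype=float)
    o = np.asarray(obs, dtype=float)
    if ens.ndim != 2 or ens.shape[0] < 2:
        raise ValueError("ensemble must be (members >= 2, times)")
    if ens.shape[1] != o.size:
        raise ValueError("ensemble and obs lengths differ")
    sigma = float(o.std(ddof=1))
    if sigma == 0:
        raise ValueError("constant observations: d-factor undefined")
    lo = (1.0 - level) / 2.0
    xl = np.quantile(ens, lo, axis=0)
    xu = np.quantile(ens, 1.0 - lo, axis=0)
    d_bar = float(np.mean(xu - xl))
    return UncertaintyResult(d_bar=d_bar, sigma_x=sigma,
                             d_factor=d_bar / sigma)
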