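"""Weekly growth indices and the annual growth index.

The weekly temperature index (TI) and moisture index (MI) are trapezoidal
responses in [0, 1]: zero at or beyond the limiting thresholds, one on
the optimal plateau, linear ramps between. The weekly growth index is
their product and the annual growth index GI_A is 100 times its mean
over the 52 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import N_WEEKS, WeeklySeries
from .hydrology import SoilMoistureSeries
from .params import SpeciesParameters

__all__ = [
    "GrowthResult",
    "trapezoid",
    "temperature_index",
    "moisture_index",
    "annual_growth_index",
    "growth_indices",
]


@dataclass
class GrowthResult:
    """Weekly TI/MI/GI plus the annual growth index (0-100)."""

    ti_w: np.ndarray
    mi_w: np.ndarray
    gi_w: np.ndarray
    gi_annual: float


def trapezoid(x, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Trapezoidal response: 0 outside (a, d), 1 on [b, c], linear ramps.

    Endpoints are closed-zero: x = a and x = d map to 0. Degenerate equal
    thresholds act as step edges (b = a gives a jump to 1 just above a;
    c = d a drop to 0 at d).
    """
    if not (a <= b <= c <= d):
        raise ValueError(f"thresholds must satisfy a <= b <= c <= d, "
                         f"got ({a}, {b}, {c}, {d})")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    out[(x >= b) & (x <= c)] = 1.0
    if b > a:
        rising = (x > a) & (x < b)
        out[rising] = (x[rising] - a) / (b - a)
    if d > c:
        falling = (x > c) & (x < d)
        out[falling] = (d - x[falling]) / (d - c)
    out[(x <= a) | (x >= d)] = 0.0
    return out


def temperature_index(weekly: WeeklySeries,
                      p: SpeciesParameters) -> np.ndarray:
    """Weekly TI: trapezoid of weekly mean temperature over dv0..dv3."""
    return trapezoid(weekly.tmean_w, p.dv0, p.dv1, p.dv2, p.dv3)


def moisture_index(sm: SoilMoistureSeries,
                   p: SpeciesParameters) -> np.ndarray:
    """Weekly MI: trapezoid of soil-moisture fraction over sm0..sm3."""
    return trapezoid(sm.sm_w, p.sm0, p.sm1, p.sm2, p.sm3)


def annual_growth_index(ti_w, mi_w) -> GrowthResult:
    """Combine weekly TI and MI into GI_A = 100 * mean(TI * MI)."""
    ti_w = np.asarray(ti_w, float)
    mi_w = np.asarray(mi_w, float)
    if ti_w.shape != (N_WEEKS,) or mi_w.shape != (N_WEEKS,):
        raise ValueError(f"TI and MI must each have {N_WEEKS} weekly values")
    gi_w = ti_w * mi_w
    return GrowthResult(ti_w=ti_w, mi_w=mi_w, gi_w=gi_w,
                        gi_annual=100.0 * float(np.sum(gi_w)) / N_WEEKS)


def growth_indices(weekly: WeeklySeries, sm: SoilMoistureSeries,
                   p: SpeciesParameters) -> GrowthResult:
    """TI, MI and GI_A for one location's weekly series."""
    return annual_growth_index(temperature_index(weekly, p),
                               moisture_index(sm, p))
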