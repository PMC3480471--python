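"""Annual stress accumulation and the combined survival index.

Each stress (cold, heat, dry, wet) accumulates linearly over the 52
weeks: the weekly exceedance of its threshold (below-threshold for cold
and dry, above for heat and wet) times a weekly rate, summed and clipped
to [0, 1]. The survival index SI is the product of (1 - stress) terms,
so any single saturated stress is lethal on its own. Accumulation is
linear rather than exponentially ramped; once a stress saturates the
downstream suitability is zero either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import N_WEEKS, WeeklySeries
from .hydrology import SoilMoistureSeries
from .params import SpeciesParameters

__all__ = ["StressResult", "accumulate_stress", "compute_stresses"]


@dataclass
class StressResult:
    """Accumulated annual stresses (each in [0, 1]) and survival index."""

    cold: float
    heat: float
    dry: float
    wet: float

    @property
    def si(self) -> float:
        return ((1.0 - self.cold) * (1.0 - self.heat)
                * (1.0 - self.dry) * (1.0 - self.wet))


def accumulate_stress(x_w, threshold: float, rate: float,
                      direction: str) -> float:
    """Linear annual stress: rate times summed weekly threshold exceedance.

    ``direction`` is ``"above"`` (exceedance = x - threshold, for heat and
    wet stress) or ``"below"`` (threshold - x, for cold and dry). The sum
    is clipped to [0, 1]; rates are magnitudes and must be non-negative.
    """
    if rate < 0:
        raise ValueError("stress rate must be a non-negative magnitude")
    x_w = np.asarray(x_w, dtype=float)
    if x_w.shape != (N_WEEKS,):
        raise ValueError(f"driver series must have {N_WEEKS} weekly values")
    if direction == "above":
        exceed = np.maximum(0.0, x_w - threshold)
    elif direction == "below":
        exceed = np.maximum(0.0, threshold - x_w)
    else:
        raise ValueError(f"direction must be 'above' or 'below', "
                         f"got {direction!r}")
    return float(np.clip(rate * exceed.sum(), 0.0, 1.0))


def compute_stresses(weekly: WeeklySeries, sm: SoilMoistureSeries,
                     p: SpeciesParameters) -> StressResult:
    """All four annual stresses for one location.

    Cold is driven by weekly minimum temperature below ttcs, heat by
    weekly maximum above tths, wet by soil moisture above smws, dry by
    soil moisture below smds (a zero rate disables a stress).
    """
    return StressResult(
        cold=accumulate_stress(weekly.tmin_w, p.ttcs, p.thcs_rate, "below"),
        heat=accumulate_stress(weekly.tmax_w, p.tths, p.thhs_rate, "above"),
        dry=accumulate_stress(sm.sm_w, p.smds, p.hds_rate, "below"),
        wet=accumulate_stress(sm.sm_w, p.smws, p.hws_rate, "above"),
    )
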