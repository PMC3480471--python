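"""Potential evapotranspiration and the soil-moisture bucket.

Weekly soil moisture — the driver of the moisture index and of wet/dry
stress — comes from a single-layer bucket: storage gains weekly
precipitation, loses weekly potential evapotranspiration (PET), and is
clipped to [0, capacity]. PET uses the Thornthwaite temperature-only
formulation without day-length correction; relative humidity is carried
in the climate model but not consumed by the default PET. The annual
cycle is spun up to a periodic steady state so the result is independent
of an arbitrary start-of-year storage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import N_WEEKS, monthly_to_weekly

__all__ = [
    "SoilMoistureSeries",
    "potential_evapotranspiration",
    "soil_moisture",
    "weekly_pet",
    "bucket_pass",
]

DEFAULT_CAPACITY_MM = 100.0
SPINUP_TOL_MM = 1e-6
SPINUP_MAX_CYCLES = 50


@dataclass
class SoilMoistureSeries:
    """Weekly soil-moisture fraction of storage capacity, with its PET."""

    sm_w: np.ndarray   # fraction in [0, 1]
    pet_w: np.ndarray  # mm/week
    capacity: float = DEFAULT_CAPACITY_MM

    def __post_init__(self) -> None:
        self.sm_w = np.asarray(self.sm_w, float)
        self.pet_w = np.asarray(self.pet_w, float)
        if self.sm_w.shape != (N_WEEKS,) or self.pet_w.shape != (N_WEEKS,):
            raise ValueError(f"series must have {N_WEEKS} weekly values")
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if np.any((self.sm_w < 0) | (self.sm_w > 1)):
            raise ValueError("sm_w must lie in [0, 1]")
        if np.any(self.pet_w < 0):
            raise ValueError("pet_w must be non-negative")


def potential_evapotranspiration(tmean_monthly) -> np.ndarray:
    """Thornthwaite monthly PET (mm/month) from monthly mean temperature.

    heat index I = sum over months with T > 0 of (T/5)^1.514;
    a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239;
    PET_m = 16 (10 max(T_m, 0) / I)^a, zero where T_m <= 0, and
    identically zero when every month is at or below freezing (I = 0).
    No day-length correction is applied.
    """
    t = np.asarray(tmean_monthly, dtype=float)
    if t.shape != (12,):
        raise ValueError("expected 12 monthly mean temperatures")
    if not np.all(np.isfinite(t)):
        raise ValueError("temperatures must be finite")
    warm = t > 0
    heat_index = np.sum((t[warm] / 5.0) ** 1.514)
    if heat_index == 0.0:
        return np.zeros(12)
    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index + 0.49239)
    pet = np.zeros(12)
    pet[warm] = 16.0 * (10.0 * t[warm] / heat_index) ** a
    return pet


def weekly_pet(tmean_monthly) -> np.ndarray:
    """Weekly PET (mm/week): monthly Thornthwaite redistributed extensively."""
    return monthly_to_weekly(potential_evapotranspiration(tmean_monthly),
                             "extensive")


def bucket_pass(s0: float, net, capacity: float) -> np.ndarray:
    """One pass of the storage recursion from initial storage ``s0``.

    S_w = clip(S_{w-1} + net_w, 0, capacity) for each element of the net
    water flux series (any length; mm).
    """
    net = np.asarray(net, float)
    out = np.empty_like(net)
    s = float(s0)
    for w, dn in enumerate(net):
        s = min(max(s + dn, 0.0), capacity)
        out[w] = s
    return out


def soil_moisture(precip_w, pet_w,
                  capacity: float = DEFAULT_CAPACITY_MM) -> SoilMoistureSeries:
    """Run the weekly bucket recursion to its periodic steady state.

    S_w = clip(S_{w-1} + precip_w - pet_w, 0, capacity); the year is
    iterated with S_0 <- S_52 from an initial half-full store until the
    start-of-year storage changes by less than 1e-6 mm (at most 50
    cycles), then sm_w = S_w / capacity.
    """
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    precip_w = np.asarray(precip_w, float)
    pet_w = np.asarray(pet_w, float)
    if precip_w.shape != (N_WEEKS,) or pet_w.shape != (N_WEEKS,):
        raise ValueError(f"expected {N_WEEKS} weekly values")
    if np.any(precip_w < 0) or np.any(pet_w < 0):
        raise ValueError("precip and PET must be non-negative")
    net = precip_w - pet_w
    s0 = capacity / 2.0
    storage = np.empty(N_WEEKS)
    for _ in range(SPINUP_MAX_CYCLES):
        storage = bucket_pass(s0, net, capacity)
        if abs(storage[-1] - s0) < SPINUP_TOL_MM:
            break
        s0 = storage[-1]
    return SoilMoistureSeries(sm_w=storage / capacity, pet_w=pet_w,
                              capacity=capacity)
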