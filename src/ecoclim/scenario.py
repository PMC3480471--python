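"""Climate-change scenarios as uniform GCM-delta perturbations.

Two global climate models are emulated by their headline 2100 deltas
under the A2 emissions pathway: CSIRO-Mk3.0 ("CS", +2.11 degC and a 14%
rainfall decrease by 2100) and MIROC-H ("MR", +4.31 degC and a 1%
rainfall decrease). Intermediate horizons interpolate linearly in time
from the 2000 baseline. The deltas are applied uniformly in space —
temperatures shifted, precipitation scaled, relative humidity held
fixed — standing in for fully gridded GCM anomaly fields.
"""

from __future__ import annotations

from dataclasses import dataclass

from .climate import ClimateGrid

__all__ = ["ScenarioSpec", "scenario_parameters", "apply_scenario", "GCMS"]

BASELINE_YEAR = 2000
HORIZON_YEAR = 2100
# (temperature delta degC at 2100, precipitation factor at 2100)
GCMS: dict[str, tuple[float, float]] = {
    "CS": (2.11, 0.86),
    "MR": (4.31, 0.99),
}


def scenario_parameters(gcm: str, year: int) -> tuple[float, float]:
    """Temperature offset (degC) and precipitation factor for (gcm, year).

    Linear in (year - 2000)/100 between the baseline identity and the
    model's 2100 endpoint; years outside [2000, 2100] are refused.
    """
    if gcm not in GCMS:
        raise ValueError(f"unknown GCM {gcm!r}; expected one of "
                         f"{sorted(GCMS)}")
    if not BASELINE_YEAR <= year <= HORIZON_YEAR:
        raise ValueError(f"year {year} outside "
                         f"[{BASELINE_YEAR}, {HORIZON_YEAR}]")
    frac = (year - BASELINE_YEAR) / (HORIZON_YEAR - BASELINE_YEAR)
    dt_2100, factor_2100 = GCMS[gcm]
    return dt_2100 * frac, 1.0 + (factor_2100 - 1.0) * frac


@dataclass(frozen=True)
class ScenarioSpec:
    """A GCM identity and horizon year, resolved to concrete deltas."""

    gcm: str
    year: int

    @property
    def delta_t(self) -> float:
        return scenario_parameters(self.gcm, self.year)[0]

    @property
    def precip_factor(self) -> float:
        return scenario_parameters(self.gcm, self.year)[1]

    def __post_init__(self) -> None:
        scenario_parameters(self.gcm, self.year)  # validate eagerly


def apply_scenario(grid: ClimateGrid, spec: ScenarioSpec) -> ClimateGrid:
    """Return a new grid with the scenario's deltas applied.

    tmin and tmax are shifted by delta_t (preserving the diurnal range),
    precipitation is scaled by the precip factor, relative humidity and
    the mask are unchanged; the input grid is not modified.
    """
    dt, pf = scenario_parameters(spec.gcm, spec.year)
    return ClimateGrid(
        lat=grid.lat.copy(), lon=grid.lon.copy(),
        tmin=grid.tmin + dt, tmax=grid.tmax + dt,
        ptotal=grid.ptotal * pf,
        rh09=grid.rh09.copy(), rh15=grid.rh15.copy(),
        mask=grid.mask.copy(),
    )
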