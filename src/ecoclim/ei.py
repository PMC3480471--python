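"""The Ecoclimatic Index: per-location pipeline, grid runs, change maps.

EI = GI_A * SI combines annual growth potential (0-100) with the
stress-mediated probability of persisting through the unfavorable
season (0-1), yielding an annual 0-100 suitability score. A species can
in principle establish wherever EI > 0. Suitability classes band the
score: unsuitable (EI = 0), marginal (0 < EI <= 10), suitable
(10 < EI <= 20), highly suitable (EI > 20); the band edges are
configurable conventions, not part of the index itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .climate import ClimateGrid, MonthlyClimate, weekly_series
from .growth import GrowthResult, growth_indices
from .hydrology import DEFAULT_CAPACITY_MM, soil_moisture, weekly_pet
from .params import SpeciesParameters
from .stress import StressResult, compute_stresses

logger = logging.getLogger(__name__)

__all__ = [
    "EIResult",
    "EIMap",
    "ChangeMap",
    "SUITABILITY_CLASSES",
    "DEFAULT_CLASS_BOUNDS",
    "classify",
    "ecoclimatic_index",
    "run_location",
    "run_grid",
    "change_map",
    "write_ei_map",
    "read_ei_map",
]

SUITABILITY_CLASSES = ("unsuitable", "marginal", "suitable",
                       "highly_suitable")
DEFAULT_CLASS_BOUNDS = (10.0, 20.0)  # marginal/suitable, suitable/highly
CHANGE_CATEGORIES = ("stable_unsuitable", "stable_suitable", "gain", "loss")
# classification applied after rounding to avoid float jitter at the bands
_CLASS_DECIMALS = 6


def classify(ei: float, bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
             ) -> str:
    """Suitability class for an EI value (rounded to 6 dp first)."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("class bounds must be strictly increasing")
    v = round(float(ei), _CLASS_DECIMALS)
    if v <= 0:
        return "unsuitable"
    if v <= lo:
        return "marginal"
    if v <= hi:
        return "suitable"
    return "highly_suitable"


@dataclass
class EIResult:
    """Full per-location outcome: growth, stresses, EI and class."""

    growth: GrowthResult
    stresses: StressResult
    ei: float
    suitability_class: str

    @property
    def gi_annual(self) -> float:
        return self.growth.gi_annual


def ecoclimatic_index(g: GrowthResult, s: StressResult,
                      class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
                      ) -> EIResult:
    """Combine growth and stress into EI = GI_A * SI and classify it."""
    ei = g.gi_annual * s.si
    return EIResult(growth=g, stresses=s, ei=ei,
                    suitability_class=classify(ei, class_bounds))


def run_location(mc: MonthlyClimate, p: SpeciesParameters,
                 capacity: float = DEFAULT_CAPACITY_MM,
                 class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
                 ) -> EIResult:
    """Deterministic per-location pipeline from monthly normals to EI.

    Stages: monthly-to-weekly interpolation, Thornthwaite PET,
    soil-moisture bucket spin-up, temperature/moisture growth indices,
    four stress accumulations, EI.
    """
    weekly = weekly_series(mc)
    tmean_monthly = (mc.tmin + mc.tmax) / 2.0
    sm = soil_moisture(weekly.precip_w, weekly_pet(tmean_monthly),
                       capacity=capacity)
    g = growth_indices(weekly, sm, p)
    s = compute_stresses(weekly, sm, p)
    return ecoclimatic_index(g, s, class_bounds)


@dataclass
class EIMap:
    """Gridded model output: EI plus its growth and stress components.

    Stress bands are on the 0-100 user scale (internal arithmetic is
    0-1). ``class_code`` indexes into SUITABILITY_CLASSES; masked cells
    hold NaN in float bands and -1 in the class band.
    """

    lat: np.ndarray
    lon: np.ndarray
    ei: np.ndarray
    gi: np.ndarray
    cold: np.ndarray
    heat: np.ndarray
    dry: np.ndarray
    wet: np.ndarray
    class_code: np.ndarray
    mask: np.ndarray
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    def class_counts(self) -> dict[str, int]:
        """Unmasked cell count per suitability class."""
        return {name: int(np.sum(self.class_code[self.mask] == code))
                for code, name in enumerate(SUITABILITY_CLASSES)}

    def same_axes(self, other: "EIMap") -> bool:
        return (self.lat.shape == other.lat.shape
                and self.lon.shape == other.lon.shape
                and np.allclose(self.lat, other.lat)
                and np.allclose(self.lon, other.lon))


def run_grid(grid: ClimateGrid, p: SpeciesParameters,
             capacity: float = DEFAULT_CAPACITY_MM,
             class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
             ) -> EIMap:
    """Run the per-location pipeline over every unmasked grid cell."""
    if not np.any(grid.mask):
        raise ValueError("grid has no unmasked cells")
    nlat, nlon = grid.shape
    bands = {name: np.full((nlat, nlon), np.nan)
             for name in ("ei", "gi", "cold", "heat", "dry", "wet")}
    class_code = np.full((nlat, nlon), -1, dtype=int)
    for i in range(nlat):
        for j in range(nlon):
            if not grid.mask[i, j]:
                continue
            r = run_location(grid.cell(i, j), p, capacity=capacity,
                             class_bounds=class_bounds)
            bands["ei"][i, j] = r.ei
            bands["gi"][i, j] = r.gi_annual
            bands["cold"][i, j] = 100.0 * r.stresses.cold
            bands["heat"][i, j] = 100.0 * r.stresses.heat
            bands["dry"][i, j] = 100.0 * r.stresses.dry
            bands["wet"][i, j] = 100.0 * r.stresses.wet
            class_code[i, j] = SUITABILITY_CLASSES.index(
                r.suitability_class)
    out = EIMap(lat=grid.lat.copy(), lon=grid.lon.copy(),
                class_code=class_code, mask=grid.mask.copy(),
                class_bounds=class_bounds, **bands)
    logger.info("run_grid: %s", out.class_counts())
    return out


@dataclass
class ChangeMap:
    """Cell-wise comparison of a future EI map against a baseline.

    Category depends only on the sign pattern of (baseline EI > 0,
    future EI > 0); ``delta_ei`` carries the signed magnitude.
    """

    lat: np.ndarray
    lon: np.ndarray
    category: np.ndarray  # index into CHANGE_CATEGORIES; -1 masked
    delta_ei: np.ndarray
    mask: np.ndarray

    def category_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.category[self.mask] == code))
                for code, name in enumerate(CHANGE_CATEGORIES)}


def change_map(base: EIMap, future: EIMap) -> ChangeMap:
    """Categorize every cell as stable/gain/loss between two runs."""
    if not base.same_axes(future):
        raise ValueError("EI maps are on different grids")
    mask = base.mask & future.mask
    b_pos = base.ei > 0
    f_pos = future.ei > 0
    category = np.full(base.shape, -1, dtype=int)
    category[mask & ~b_pos & ~f_pos] = 0  # stable_unsuitable
    category[mask & b_pos & f_pos] = 1    # stable_suitable
    category[mask & ~b_pos & f_pos] = 2   # gain
    category[mask & b_pos & ~f_pos] = 3   # loss
    delta = np.where(mask, future.ei - base.ei, np.nan)
    return ChangeMap(lat=base.lat.copy(), lon=base.lon.copy(),
                     category=category, delta_ei=delta, mask=mask)


_EI_BANDS = ("ei", "gi", "cold", "heat", "dry", "wet")


def write_ei_map(m: EIMap, path: str | Path,
                 format: str | None = None) -> None:
    """Write an EI map as NetCDF (scipy engine) or long-format CSV."""
    path = Path(path)
    if format is None:
        format = "netcdf" if path.suffix in {".nc", ".nc4"} else "csv"
    if format == "netcdf":
        ds = xr.Dataset(
            {b: (("lat", "lon"), getattr(m, b)) for b in _EI_BANDS}
            | {"class_code": (("lat", "lon"), m.class_code)},
            coords={"lat": m.lat, "lon": m.lon},
            attrs={"class_bounds": [float(b) for b in m.class_bounds],
                   "classes": ",".join(SUITABILITY_CLASSES)},
        )
        ds.to_netcdf(path, engine="scipy")
    elif format == "csv":
        ii, jj = np.where(m.mask)
        df = pd.DataFrame({"lat": m.lat[ii], "lon": m.lon[jj]})
        for b in _EI_BANDS:
            df[b] = getattr(m, b)[ii, jj]
        df["suitability_class"] = [SUITABILITY_CLASSES[c]
                                   for c in m.class_code[ii, jj]]
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown EI map format {format!r}")


def read_ei_map(path: str | Path) -> EIMap:
    """Read back an EI map written as NetCDF."""
    ds = xr.open_dataset(path, engine="scipy")
    bands = {b: ds[b].to_numpy() for b in _EI_BANDS}
    class_code = ds["class_code"].to_numpy().astype(int)
    mask = np.isfinite(bands["ei"])
    bounds = tuple(ds.attrs.get("class_bounds", DEFAULT_CLASS_BOUNDS))
    m = EIMap(lat=ds["lat"].to_numpy(), lon=ds["lon"].to_numpy(),
              class_code=class_code, mask=mask, class_bounds=bounds, **bands)
    ds.close()
    return m
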