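"""Monthly climate normals: data model, I/O, and weekly interpolation.

The engine runs on a 52-week year, but climate normals come as 12 monthly
values per variable. :func:`monthly_to_weekly` bridges the two:

* *intensive* quantities (temperature, relative humidity) are interpolated
  circularly through month-midpoint anchors and sampled at week midpoints;
* *extensive* quantities (precipitation totals in mm/month) are
  redistributed over the weeks in proportion to the calendar overlap of
  each week with each month, which conserves the annual total exactly and
  keeps the operation linear in its input.

The year is 365 days split into 52 equal weeks of 365/52 days; standard
month lengths are used for the anchors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "MonthlyClimate",
    "ClimateGrid",
    "WeeklySeries",
    "N_WEEKS",
    "MONTH_DAYS",
    "monthly_to_weekly",
    "weekly_series",
    "read_climate",
    "write_climate",
]

N_WEEKS = 52
YEAR_DAYS = 365.0
WEEK_DAYS = YEAR_DAYS / N_WEEKS
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)
_MONTH_EDGES = np.concatenate([[0.0], np.cumsum(MONTH_DAYS)])
_MONTH_MID = (_MONTH_EDGES[:-1] + _MONTH_EDGES[1:]) / 2.0
_WEEK_EDGES = np.arange(N_WEEKS + 1) * WEEK_DAYS
_WEEK_MID = (_WEEK_EDGES[:-1] + _WEEK_EDGES[1:]) / 2.0

CLIMATE_VARS = ("tmin", "tmax", "ptotal", "rh09", "rh15")


@dataclass
class MonthlyClimate:
    """Twelve-month climate normals for one location.

    tmin/tmax in deg C, ptotal in mm/month, rh09/rh15 in percent.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    ptotal: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    lat: float = 0.0
    lon: float = 0.0

    def __post_init__(self) -> None:
        for name in CLIMATE_VARS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
            setattr(self, name, arr)

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty if valid)."""
        problems = []
        if not np.all(np.isfinite(np.concatenate(
                [getattr(self, v) for v in CLIMATE_VARS]))):
            problems.append("non-finite value")
        if np.any(self.tmax < self.tmin):
            problems.append("tmax < tmin")
        if np.any(self.ptotal < 0):
            problems.append("negative precipitation")
        for name in ("rh09", "rh15"):
            rh = getattr(self, name)
            if np.any((rh < 0) | (rh > 100)):
                problems.append(f"{name} outside [0, 100]")
        if not -90 <= self.lat <= 90:
            problems.append("lat outside [-90, 90]")
        if not -180 <= self.lon <= 180:
            problems.append("lon outside [-180, 180]")
        return problems


@dataclass
class WeeklySeries:
    """52-week series interpolated from monthly normals for one location."""

    tmin_w: np.ndarray
    tmax_w: np.ndarray
    precip_w: np.ndarray  # mm/week
    rh_w: np.ndarray      # percent, mean of 09:00 and 15:00 levels

    def __post_init__(self) -> None:
        for name in ("tmin_w", "tmax_w", "precip_w", "rh_w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_WEEKS,):
                raise ValueError(f"{name} must have {N_WEEKS} weekly values")
            setattr(self, name, arr)

    @property
    def tmean_w(self) -> np.ndarray:
        return (self.tmin_w + self.tmax_w) / 2.0


@dataclass
class ClimateGrid:
    """Regular lat/lon grid of monthly climate normals.

    ``lat``/``lon`` are strictly monotonic cell-center coordinates in
    decimal degrees (WGS84 assumed). Variable arrays are shaped
    ``(12, nlat, nlon)``. ``mask`` is True where a cell holds valid data.
    """

    lat: np.ndarray
    lon: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    ptotal: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, float)
        self.lon = np.asarray(self.lon, float)
        for ax, name in [(self.lat, "lat"), (self.lon, "lon")]:
            d = np.diff(ax)
            if ax.ndim != 1 or (not np.all(d > 0) and not np.all(d < 0)):
                raise ValueError(f"{name} axis must be strictly monotonic")
        shape = (12, self.lat.size, self.lon.size)
        for name in CLIMATE_VARS:
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if self.mask is None:
            self.mask = np.ones((self.lat.size, self.lon.size), bool)
        else:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != (self.lat.size, self.lon.size):
                raise ValueError("mask shape must match (nlat, nlon)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    def cell(self, i: int, j: int) -> MonthlyClimate:
        """Monthly record for grid cell (i, j)."""
        return MonthlyClimate(
            tmin=self.tmin[:, i, j], tmax=self.tmax[:, i, j],
            ptotal=self.ptotal[:, i, j], rh09=self.rh09[:, i, j],
            rh15=self.rh15[:, i, j],
            lat=float(self.lat[i]), lon=float(self.lon[j]),
        )

    def validate_cells(self) -> int:
        """Mask cells violating per-cell invariants; return count masked."""
        n_masked = 0
        for i in range(self.lat.size):
            for j in range(self.lon.size):
                if not self.mask[i, j]:
                    continue
                problems = self.cell(i, j).validate()
                if problems:
                    self.mask[i, j] = False
                    n_masked += 1
                    logger.warning(
                        "masking cell (%.3f, %.3f): %s",
                        self.lat[i], self.lon[j], "; ".join(problems),
                    )
        return n_masked


def monthly_to_weekly(values, kind: str) -> np.ndarray:
    """Convert 12 monthly values to 52 weekly values.

    Parameters
    ----------
    values
        12 finite per-month values.
    kind
        ``"intensive"`` (temperature-like: circular piecewise-linear
        interpolation through month midpoints, sampled at week midpoints)
        or ``"extensive"`` (total-like, e.g. mm/month: overlap-weighted
        redistribution conserving the annual sum exactly).
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (12,):
        raise ValueError("expected 12 monthly values")
    if not np.all(np.isfinite(v)):
        raise ValueError("monthly values must be finite")
    if kind == "intensive":
        # wrap anchors one year each way for circular interpolation
        x = np.concatenate([_MONTH_MID - YEAR_DAYS, _MONTH_MID,
                            _MONTH_MID + YEAR_DAYS])
        y = np.concatenate([v, v, v])
        return np.interp(_WEEK_MID, x, y)
    if kind == "extensive":
        return _OVERLAP @ v
    raise ValueError(f"unknown kind {kind!r}; use 'intensive' or 'extensive'")


def _overlap_matrix() -> np.ndarray:
    """(52, 12) matrix: fraction of month m's total falling in week w."""
    out = np.zeros((N_WEEKS, 12))
    for w in range(N_WEEKS):
        w0, w1 = _WEEK_EDGES[w], _WEEK_EDGES[w + 1]
        for m in range(12):
            m0, m1 = _MONTH_EDGES[m], _MONTH_EDGES[m + 1]
            ov = max(0.0, min(w1, m1) - max(w0, m0))
            out[w, m] = ov / MONTH_DAYS[m]
    return out


_OVERLAP = _overlap_matrix()


def weekly_series(mc: MonthlyClimate) -> WeeklySeries:
    """Interpolate a monthly record into the engine's weekly series."""
    rh_monthly = (mc.rh09 + mc.rh15) / 2.0
    return WeeklySeries(
        tmin_w=monthly_to_weekly(mc.tmin, "intensive"),
        tmax_w=monthly_to_weekly(mc.tmax, "intensive"),
        precip_w=monthly_to_weekly(mc.ptotal, "extensive"),
        rh_w=monthly_to_weekly(rh_monthly, "intensive"),
    )


def grid_to_frame(grid: ClimateGrid) -> pd.DataFrame:
    """Long-format table (lat, lon, month, tmin, tmax, ptotal, rh09, rh15)."""
    rows = []
    for i in range(grid.lat.size):
        for j in range(grid.lon.size):
            if not grid.mask[i, j]:
                continue
            for m in range(12):
                rows.append({
                    "lat": grid.lat[i], "lon": grid.lon[j], "month": m + 1,
                    **{v: getattr(grid, v)[m, i, j] for v in CLIMATE_VARS},
                })
    return pd.DataFrame(rows)


def read_climate(path: str | Path, format: str | None = None) -> ClimateGrid:
    """Read a climate grid from long-format CSV or NetCDF.

    Cells violating per-cell invariants are masked with a logged warning
    rather than rejected.
    """
    path = Path(path)
    if format is None:
        format = "netcdf" if path.suffix in {".nc", ".nc4", ".cdf"} else "csv"
    if format == "csv":
        grid = _read_csv(path)
    elif format == "netcdf":
        grid = _read_netcdf(path)
    else:
        raise ValueError(f"unknown climate format {format!r}")
    grid.validate_cells()
    return grid


def _read_csv(path: Path) -> ClimateGrid:
    df = pd.read_csv(path)
    required = {"lat", "lon", "month", *CLIMATE_VARS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    ilat = pd.Index(lat)
    ilon = pd.Index(lon)
    shape = (12, lat.size, lon.size)
    arrays = {v: np.full(shape, np.nan) for v in CLIMATE_VARS}
    i = ilat.get_indexer(df["lat"])
    j = ilon.get_indexer(df["lon"])
    m = df["month"].to_numpy(int) - 1
    if np.any((m < 0) | (m > 11)):
        raise ValueError("month column must be in 1..12")
    for v in CLIMATE_VARS:
        arrays[v][m, i, j] = df[v].to_numpy(float)
    mask = np.all([np.all(np.isfinite(arrays[v]), axis=0)
                   for v in CLIMATE_VARS], axis=0)
    return ClimateGrid(lat=lat, lon=lon, mask=mask, **arrays)


def _read_netcdf(path: Path) -> ClimateGrid:
    ds = xr.open_dataset(path, engine="scipy")
    missing = [v for v in CLIMATE_VARS if v not in ds]
    if missing:
        raise ValueError(f"climate NetCDF missing variables: {missing}")
    arrays = {v: ds[v].transpose("month", "lat", "lon").to_numpy()
              for v in CLIMATE_VARS}
    mask = np.all([np.all(np.isfinite(arrays[v]), axis=0)
                   for v in CLIMATE_VARS], axis=0)
    grid = ClimateGrid(lat=ds["lat"].to_numpy(), lon=ds["lon"].to_numpy(),
                       mask=mask, **arrays)
    ds.close()
    return grid


def write_climate(grid: ClimateGrid, path: str | Path,
                  format: str | None = None) -> None:
    """Write a climate grid as long-format CSV or NetCDF (scipy engine)."""
    path = Path(path)
    if format is None:
        format = "netcdf" if path.suffix in {".nc", ".nc4", ".cdf"} else "csv"
    if format == "csv":
        grid_to_frame(grid).to_csv(path, index=False)
    elif format == "netcdf":
        data = {}
        for v in CLIMATE_VARS:
            arr = getattr(grid, v).copy()
            arr[:, ~grid.mask] = np.nan
            data[v] = (("month", "lat", "lon"), arr)
        ds = xr.Dataset(
            data,
            coords={"month": np.arange(1, 13), "lat": grid.lat,
                    "lon": grid.lon},
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown climate format {format!r}")
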