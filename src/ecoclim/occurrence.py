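"""Occurrence-record cleaning, model validation, and a fit score.

Occurrence catalogues arrive contaminated in predictable ways: records
with no coordinates, records with impossible coordinates, and exact
duplicates. The cleaning here mirrors the standard pipeline — drop
records missing either coordinate, drop out-of-range coordinates,
collapse duplicates at a fixed coordinate precision — and the
validation stage scores a suitability map against the cleaned presences
by nearest-cell lookup.

Records travel as pandas DataFrames with columns id, lat, lon, source;
missing coordinates are NaN/empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ei import EIMap
from .params import SpeciesParameters

logger = logging.getLogger(__name__)

__all__ = [
    "FilterResult",
    "ValidationReport",
    "read_occurrences",
    "write_occurrences",
    "filter_missing_coordinates",
    "deduplicate",
    "validate_model",
    "fit_score",
]

OCCURRENCE_COLUMNS = ("id", "lat", "lon", "source")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an occurrence CSV/TSV (columns id, lat, lon, source)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(OCCURRENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: "
                         f"{sorted(missing)}")
    return df[list(OCCURRENCE_COLUMNS)]


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


@dataclass
class FilterResult:
    """Cleaned records plus counts of what was removed and why."""

    records: pd.DataFrame
    n_missing: int   # lacked one or both coordinates
    n_invalid: int   # coordinates present but out of range


def filter_missing_coordinates(records: pd.DataFrame) -> FilterResult:
    """Retain records with both coordinates present and in valid range.

    Order is preserved; records missing a coordinate and records with
    out-of-range coordinates are counted separately.
    """
    lat = pd.to_numeric(records["lat"], errors="coerce")
    lon = pd.to_numeric(records["lon"], errors="coerce")
    present = lat.notna() & lon.notna()
    in_range = lat.between(-90, 90) & lon.between(-180, 180)
    keep = present & in_range
    out = records.loc[keep].copy()
    out["lat"] = lat[keep]
    out["lon"] = lon[keep]
    return FilterResult(
        records=out,
        n_missing=int((~present).sum()),
        n_invalid=int((present & ~in_range).sum()),
    )


def deduplicate(records: pd.DataFrame, precision: int = 4) -> pd.DataFrame:
    """Collapse records identical after rounding lat/lon to `precision` dp.

    The first occurrence wins; at 4 decimal places two records must sit
    within roughly 11 m to collapse.
    """
    if records.empty:
        return records.copy()
    key = list(zip(records["lat"].round(precision),
                   records["lon"].round(precision)))
    return records.loc[~pd.Series(key, index=records.index).duplicated()]


@dataclass
class ValidationReport:
    """How well an EI map agrees with presence records."""

    n_records: int               # records offered (inside or outside grid)
    n_used: int                  # records inside the grid bounds
    n_outside: int               # excluded as outside the grid
    fraction_ei_positive: float  # share of used records with EI > 0
    mean_ei_at_presence: float
    omission_at_marginal: float  # share of used records with EI <= 10

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_records", "n_used", "n_outside", "fraction_ei_positive",
            "mean_ei_at_presence", "omission_at_marginal")}


def _nearest_indices(axis: np.ndarray, coords: np.ndarray) -> np.ndarray:
    # argmin over |axis - coord|; ties resolve to the lower index
    return np.argmin(np.abs(axis[None, :] - coords[:, None]), axis=1)


def _within_bounds(axis: np.ndarray, coords: np.ndarray) -> np.ndarray:
    half = np.median(np.abs(np.diff(axis))) / 2.0
    lo, hi = min(axis[0], axis[-1]) - half, max(axis[0], axis[-1]) + half
    return (coords >= lo) & (coords <= hi)


def validate_model(ei_map: EIMap, records: pd.DataFrame,
                   marginal_ei: float = 10.0) -> ValidationReport:
    """Score an EI map against presence records by nearest-cell lookup.

    Records outside the grid's bounds are excluded with a warning but
    counted in the report; masked cells count as outside.
    """
    if records.empty:
        raise ValueError("no occurrence records to validate against")
    lat = records["lat"].to_numpy(float)
    lon = records["lon"].to_numpy(float)
    inside = (_within_bounds(ei_map.lat, lat)
              & _within_bounds(ei_map.lon, lon))
    ii = _nearest_indices(ei_map.lat, lat[inside])
    jj = _nearest_indices(ei_map.lon, lon[inside])
    on_valid = ei_map.mask[ii, jj]
    ei = ei_map.ei[ii[on_valid], jj[on_valid]]
    n_outside = int((~inside).sum()) + int((~on_valid).sum())
    if n_outside:
        logger.warning("%d record(s) outside the grid or on masked cells; "
                       "excluded from validation", n_outside)
    if ei.size == 0:
        raise ValueError("no records fall on valid grid cells")
    return ValidationReport(
        n_records=len(records),
        n_used=int(ei.size),
        n_outside=n_outside,
        fraction_ei_positive=float(np.mean(ei > 0)),
        mean_ei_at_presence=float(np.mean(ei)),
        omission_at_marginal=float(np.mean(ei <= marginal_ei)),
    )


def fit_score(p: SpeciesParameters, grid, records: pd.DataFrame,
              area_penalty: float = 0.5) -> float:
    """Presence agreement minus an area penalty, for manual fitting.

    score = (fraction of presences with EI > 0)
            - area_penalty * (fraction of unmasked cells with EI > 0).
    Higher is better: a parameter set that covers the presences with the
    smallest suitable footprint wins. Deterministic given its inputs.
    """
    from .ei import run_grid  # local import to avoid cycle at module load

    ei_map = run_grid(grid, p)
    report = validate_model(ei_map, records)
    suitable_fraction = float(np.mean(ei_map.ei[ei_map.mask] > 0))
    return report.fraction_ei_positive - area_penalty * suitable_fraction
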