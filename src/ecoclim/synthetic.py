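"""Synthetic climates and occurrence catalogues for end-to-end testing.

Nothing here downloads anything. Three generators provide the inputs the
analysis needs, with the statistical structure real data would have:

* :func:`make_station` — one monthly-normals record drawn from a named
  climate archetype (sinusoidal seasonal cycle, archetype precipitation
  profile, optional seeded Gaussian jitter);
* :func:`make_world` — a regular lat/lon grid with a latitudinal
  temperature gradient (warm equator, cold poles, seasonal amplitude
  growing poleward) and zonal precipitation bands (wet equator, dry
  subtropics, moderate mid-latitudes);
* :func:`make_occurrences` — presence records importance-sampled in
  proportion to a model's Ecoclimatic Index, then contaminated with
  blanked coordinates and exact duplicates the way public occurrence
  databases are.

All randomness flows through numpy's seeded PCG64 generator; the same
seed reproduces the same output bit for bit on any platform. The
archetype constants below are the package's ground truth: tests assert
the properties the constants were chosen to produce (e.g. the
cool-temperate mean temperature never reaches the date-palm limiting
low), referencing the constants symbolically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateGrid, MonthlyClimate
from .params import SpeciesParameters

__all__ = ["ClimateArchetype", "ARCHETYPES", "make_station",
           "make_constant_station", "make_optimal_station", "make_world",
           "make_occurrences"]


@dataclass(frozen=True)
class ClimateArchetype:
    """Fixed constants describing one idealized climate.

    ``tmean_annual`` and ``seasonal_amplitude`` in degC (monthly mean =
    annual - amplitude * cos(2 pi m / 12), July-peaked); ``diurnal_range``
    degC between tmax and tmin; ``precip_profile`` in mm/month, Jan..Dec;
    ``rh09``/``rh15`` percent.
    """

    name: str
    tmean_annual: float
    seasonal_amplitude: float
    diurnal_range: float
    precip_profile: tuple[float, ...]
    rh09: float
    rh15: float


ARCHETYPES: dict[str, ClimateArchetype] = {
    # monthly tmean spans 22-36 degC (inside the date-palm optimal band);
    # sparse winter-peaked rain keeps the bucket wet part of the year only
    "hot_desert": ClimateArchetype(
        "hot_desert", tmean_annual=29.0, seasonal_amplitude=7.0,
        diurnal_range=14.0,
        precip_profile=(60, 55, 45, 20, 5, 0, 0, 0, 2, 10, 30, 55),
        rh09=35.0, rh15=20.0),
    "mediterranean": ClimateArchetype(
        "mediterranean", tmean_annual=16.0, seasonal_amplitude=8.0,
        diurnal_range=10.0,
        precip_profile=(90, 80, 70, 50, 30, 10, 5, 5, 30, 60, 80, 90),
        rh09=75.0, rh15=55.0),
    # monthly tmean spans -2..12 degC: never reaches 14 degC
    "cool_temperate": ClimateArchetype(
        "cool_temperate", tmean_annual=5.0, seasonal_amplitude=7.0,
        diurnal_range=8.0,
        precip_profile=(70,) * 12,
        rh09=85.0, rh15=70.0),
    # rain far exceeds evaporative demand: soil stays near saturation
    "wet_tropical": ClimateArchetype(
        "wet_tropical", tmean_annual=26.0, seasonal_amplitude=2.0,
        diurnal_range=8.0,
        precip_profile=(250,) * 12,
        rh09=95.0, rh15=80.0),
}

_MONTH_PHASE = np.cos(2.0 * np.pi * np.arange(12) / 12.0)

# Synthetic-world constants (the generator's ground truth).
WORLD_EQUATOR_TMEAN = 28.0       # degC annual mean at the equator
WORLD_LAPSE_PER_DEG = 0.6        # degC decrease per degree latitude
WORLD_AMPLITUDE_PER_DEG = 0.25   # seasonal amplitude growth per degree
WORLD_DIURNAL_RANGE = 12.0       # degC
WORLD_TMEAN_NOISE_SD = 0.3       # degC jitter on the annual mean
WORLD_PRECIP_NOISE_SD = 0.05     # relative jitter on precipitation
# zonal precipitation bands: |lat| nodes -> annual mm
_PRECIP_LAT_NODES = np.array([0.0, 15.0, 25.0, 35.0, 50.0, 70.0, 90.0])
_PRECIP_LAT_MM = np.array([2000.0, 1200.0, 200.0, 400.0, 800.0,
                           600.0, 300.0])


def world_annual_tmean(lat) -> np.ndarray:
    """Noise-free annual mean temperature of the synthetic world."""
    return WORLD_EQUATOR_TMEAN - WORLD_LAPSE_PER_DEG * np.abs(lat)


def world_seasonal_amplitude(lat) -> np.ndarray:
    return WORLD_AMPLITUDE_PER_DEG * np.abs(lat)


def make_station(archetype: str, jitter_sd: float = 0.0,
                 seed: int = 0, lat: float = 0.0,
                 lon: float = 0.0) -> MonthlyClimate:
    """One monthly-normals record drawn from a named archetype.

    ``jitter_sd`` adds seeded Gaussian noise (degC on monthly mean
    temperature, percentage points on RH, relative on precipitation);
    zero jitter is fully deterministic. Invariants hold by construction:
    tmax = tmean + diurnal/2 >= tmin = tmean - diurnal/2, RH clipped to
    [0, 100], precipitation floored at 0.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of "
                         f"{sorted(ARCHETYPES)}")
    a = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    tmean = a.tmean_annual - a.seasonal_amplitude * _MONTH_PHASE
    precip = np.asarray(a.precip_profile, float).copy()
    rh09 = np.full(12, a.rh09)
    rh15 = np.full(12, a.rh15)
    if jitter_sd > 0:
        tmean = tmean + rng.normal(0.0, jitter_sd, 12)
        precip = np.maximum(
            0.0, precip * (1.0 + rng.normal(0.0, jitter_sd / 10.0, 12)))
        rh09 = np.clip(rh09 + rng.normal(0.0, jitter_sd, 12), 0, 100)
        rh15 = np.clip(rh15 + rng.normal(0.0, jitter_sd, 12), 0, 100)
    half = a.diurnal_range / 2.0
    return MonthlyClimate(tmin=tmean - half, tmax=tmean + half,
                          ptotal=precip, rh09=rh09, rh15=rh15,
                          lat=lat, lon=lon)


def make_constant_station(tmean: float, diurnal_range: float = 10.0,
                          precip_monthly=0.0, rh: float = 50.0,
                          lat: float = 0.0, lon: float = 0.0
                          ) -> MonthlyClimate:
    """Season-free monthly record: one mean temperature all year.

    ``precip_monthly`` may be a scalar (uniform mm/month) or a 12-vector.
    Useful for constructing boundary-condition climates (e.g. a year held
    entirely inside, or entirely outside, a species' optimal bands).
    """
    tmean_m = np.full(12, float(tmean))
    precip = np.broadcast_to(np.asarray(precip_monthly, float),
                             (12,)).copy()
    half = diurnal_range / 2.0
    return MonthlyClimate(tmin=tmean_m - half, tmax=tmean_m + half,
                          ptotal=precip, rh09=np.full(12, rh),
                          rh15=np.full(12, rh), lat=lat, lon=lon)


def make_optimal_station(p: SpeciesParameters,
                         diurnal_range: float = 10.0) -> MonthlyClimate:
    """Constant climate held inside every optimal band of a parameter set.

    Mean temperature sits at the middle of the optimal plateau
    (dv1..dv2); monthly rain alternates +-10 mm around the monthly
    Thornthwaite demand so the half-full soil bucket oscillates mid-band
    without approaching saturation or wilting. Under a parameter set
    whose stress thresholds are not crossed by this construction (true
    of the date-palm defaults) the resulting Ecoclimatic Index is the
    scale maximum.
    """
    from .hydrology import potential_evapotranspiration

    tmean = (p.dv1 + p.dv2) / 2.0
    pet = potential_evapotranspiration(np.full(12, tmean))
    precip = pet + 10.0 * np.where(np.arange(12) % 2 == 0, 1.0, -1.0)
    return make_constant_station(tmean, diurnal_range=diurnal_range,
                                 precip_monthly=np.maximum(precip, 0.0))


def make_world(n_lat: int = 36, n_lon: int = 72,
               seed: int = 0) -> ClimateGrid:
    """Synthetic global grid with a latitudinal climate gradient.

    Annual mean temperature falls linearly poleward from the equator,
    seasonal amplitude grows poleward (southern-hemisphere seasons are
    phase-flipped), and annual precipitation follows zonal bands
    interpolated over |latitude|. Seeded noise perturbs the annual mean
    and precipitation; every cell is valid by construction.
    """
    if n_lat < 2 or n_lon < 2:
        raise ValueError("need at least a 2x2 grid")
    rng = np.random.default_rng(seed)
    dlat, dlon = 180.0 / n_lat, 360.0 / n_lon
    lat = 90.0 - dlat / 2.0 - dlat * np.arange(n_lat)  # north to south
    lon = -180.0 + dlon / 2.0 + dlon * np.arange(n_lon)
    amp = world_seasonal_amplitude(lat)
    annual_p = np.interp(np.abs(lat), _PRECIP_LAT_NODES, _PRECIP_LAT_MM)
    tmean_noise = rng.normal(0.0, WORLD_TMEAN_NOISE_SD, (n_lat, n_lon))
    precip_noise = rng.normal(0.0, WORLD_PRECIP_NOISE_SD, (n_lat, n_lon))
    shape = (12, n_lat, n_lon)
    tmin = np.empty(shape)
    tmax = np.empty(shape)
    ptotal = np.empty(shape)
    half = WORLD_DIURNAL_RANGE / 2.0
    # July-peaked north of the equator, January-peaked south of it
    phase_sign = np.where(lat >= 0, -1.0, 1.0)
    for m in range(12):
        season = phase_sign * _MONTH_PHASE[m] * amp          # (n_lat,)
        tmean_m = (world_annual_tmean(lat) + season)[:, None] + tmean_noise
        tmin[m] = tmean_m - half
        tmax[m] = tmean_m + half
        ptotal[m] = np.maximum(
            0.0, (annual_p[:, None] / 12.0) * (1.0 + precip_noise))
    rh09 = np.full(shape, 70.0)
    rh15 = np.full(shape, 50.0)
    return ClimateGrid(lat=lat, lon=lon, tmin=tmin, tmax=tmax,
                       ptotal=ptotal, rh09=rh09, rh15=rh15)


def make_occurrences(grid: ClimateGrid, p: SpeciesParameters, n: int,
                     missing_frac: float = 0.0, dup_frac: float = 0.0,
                     seed: int = 0) -> pd.DataFrame:
    """Presence catalogue importance-sampled from a model's EI surface.

    ``n`` presences are drawn over unmasked cells with probability
    proportional to EI, jittered uniformly within their cell. Then
    round(missing_frac * n) records get their coordinates blanked and
    round(dup_frac * n) exact duplicates are appended. Contamination
    counts live in the frame's ``attrs`` (n_missing, n_duplicates).
    Raises if the whole grid has EI = 0 (nothing to sample).
    """
    from .ei import run_grid

    if n < 1:
        raise ValueError("n must be >= 1")
    for name, frac in [("missing_frac", missing_frac),
                       ("dup_frac", dup_frac)]:
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    ei_map = run_grid(grid, p)
    ii, jj = np.where(ei_map.mask & (ei_map.ei > 0))
    if ii.size == 0:
        raise ValueError("grid has no cells with EI > 0; nothing to sample")
    weights = ei_map.ei[ii, jj]
    rng = np.random.default_rng(seed)
    pick = rng.choice(ii.size, size=n, replace=True,
                      p=weights / weights.sum())
    dlat = np.median(np.abs(np.diff(ei_map.lat)))
    dlon = np.median(np.abs(np.diff(ei_map.lon)))
    lat = (ei_map.lat[ii[pick]]
           + rng.uniform(-dlat / 2, dlat / 2, n))
    lon = (ei_map.lon[jj[pick]]
           + rng.uniform(-dlon / 2, dlon / 2, n))
    df = pd.DataFrame({
        "id": [f"occ{k:05d}" for k in range(n)],
        "lat": lat, "lon": lon,
        "source": "gbif-like",
    })
    n_missing = int(round(missing_frac * n))
    if n_missing:
        blank = rng.choice(n, size=n_missing, replace=False)
        df.loc[blank, ["lat", "lon"]] = np.nan
    n_dup = int(round(dup_frac * n))
    if n_dup:
        complete = df.index[df["lat"].notna()]
        dups = df.loc[rng.choice(complete, size=n_dup, replace=True)].copy()
        dups["id"] = [f"dup{k:05d}" for k in range(n_dup)]
        df = pd.concat([df, dups], ignore_index=True)
    df.attrs["n_missing"] = n_missing
    df.attrs["n_duplicates"] = n_dup
    return df
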