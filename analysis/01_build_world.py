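#!/usr/bin/env python
"""Build the synthetic study inputs: a gridded world and an occurrence
catalogue with realistic contamination.

Writes the full climate grid to scratch/ (it is regenerable from the
seed) and a small summary of the world plus the raw occurrence table to
results/.
"""

import json
from pathlib import Path

import numpy as np

from ecoclim.climate import write_climate
from ecoclim.occurrence import write_occurrences
from ecoclim.params import date_palm_defaults
from ecoclim.synthetic import make_occurrences, make_world

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    palm = date_palm_defaults()

    world = make_world(n_lat=36, n_lon=72, seed=SEED)
    write_climate(world, SCRATCH / "world_climate.csv")
    write_climate(world, SCRATCH / "world_climate.nc")

    # catalogue mirrors the contamination structure of a raw public
    # occurrence pull: 583 records, 342 without coordinates, plus a
    # block of exact duplicates among the complete ones
    occ = make_occurrences(world, palm, n=583, missing_frac=342 / 583,
                           dup_frac=0.10, seed=SEED)
    write_occurrences(occ, RESULTS / "occurrences_raw.csv")

    tmean = (world.tmin + world.tmax) / 2.0
    summary = {
        "seed": SEED,
        "grid": {"n_lat": 36, "n_lon": 72,
                 "lat_range": [float(world.lat.min()),
                               float(world.lat.max())],
                 "tmean_range_degC": [float(tmean.min()),
                                      float(tmean.max())],
                 "annual_precip_range_mm": [
                     float(world.ptotal.sum(axis=0).min()),
                     float(world.ptotal.sum(axis=0).max())]},
        "occurrences": {"n_records": len(occ),
                        "n_missing_coordinates": occ.attrs["n_missing"],
                        "n_duplicates_appended": occ.attrs["n_duplicates"]},
    }
    (RESULTS / "world_summary.json").write_text(
        json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print(f"full climate grid -> {SCRATCH / 'world_climate.nc'}")

if __name__ == "__main__":
    main()
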