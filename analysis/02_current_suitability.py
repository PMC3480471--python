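#!/usr/bin/env python
"""Model current-climate suitability on the synthetic world and validate
it against the cleaned occurrence catalogue.

Reads the world and raw occurrences produced by 01_build_world.py
(regenerating the world from its seed if scratch/ was cleaned), runs
the Ecoclimatic Index over the grid, cleans the catalogue
(coordinate filter, then deduplication), and scores the map against the
presences. Full rasters go to scratch/; class counts, the cleaning
trail, and the validation report go to results/.
"""

import json
from pathlib import Path

import numpy as np

from ecoclim.ei import run_grid, write_ei_map
from ecoclim.occurrence import (deduplicate, filter_missing_coordinates,
                                read_occurrences, validate_model)
from ecoclim.params import date_palm_defaults
from ecoclim.synthetic import make_world

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    palm = date_palm_defaults()
    world = make_world(n_lat=36, n_lon=72, seed=SEED)

    ei_map = run_grid(world, palm)
    write_ei_map(ei_map, SCRATCH / "ei_current.nc")
    counts = ei_map.class_counts()
    pos = ei_map.ei > 0
    band_lats = np.abs(ei_map.lat[np.where(pos.any(axis=1))[0]])
    print(f"current climate: {int(pos.sum())} of {pos.size} cells have "
          f"EI > 0; suitable band reaches |lat| = {band_lats.max():.1f}")

    occ = read_occurrences(RESULTS / "occurrences_raw.csv")
    filt = filter_missing_coordinates(occ)
    clean = deduplicate(filt.records)
    print(f"occurrences: {len(occ)} raw -> {len(filt.records)} with "
          f"coordinates -> {len(clean)} after deduplication")
    report = validate_model(ei_map, clean)
    bg_mean = float(np.mean(ei_map.ei[ei_map.mask]))
    print(f"validation: {report.fraction_ei_positive:.1%} of presences on "
          f"EI > 0 cells; mean EI at presence {report.mean_ei_at_presence:.1f} "
          f"vs grid background {bg_mean:.1f}")

    payload = {
        "class_counts": counts,
        "suitable_band_max_abs_lat": float(band_lats.max()),
        "cleaning": {"n_raw": len(occ),
                     "n_missing_coordinates": filt.n_missing,
                     "n_invalid_coordinates": filt.n_invalid,
                     "n_after_filter": len(filt.records),
                     "n_after_dedup": len(clean)},
        "validation": report.to_dict(),
        "background_mean_ei": bg_mean,
    }
    (RESULTS / "current_suitability.json").write_text(
        json.dumps(payload, indent=2))

if __name__ == "__main__":
    main()
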