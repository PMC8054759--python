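#!/usr/bin/env python
"""Infer seasonal migratory corridors with three methods and their consensus.

Builds spring (Mar-May) and fall (Aug-Oct) conductance surfaces from the
monthly ensembles, then runs: all-pairs least-cost paths between the
winter (Dec-Feb) and summer (Jun-Jul) occurrence points with density
aggregation; a circuit-theory current map (sources and grounds set by the
hypothesized migration direction); and the 95th-percentile suitability
mask.  Cells flagged by all three are the consensus corridor.  Writes the
corridor rasters, the path table and geometries under results/05_corridors/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import CFG, CORRIDORS, MODELS, OCCURRENCES

from corridorscape.connectivity import (
    build_graph,
    consensus_overlap,
    lcp_density,
    percentile_mask,
    seasonal_conductance,
    solve_current,
)
from corridorscape.occurrences import grid_thin, read_occurrences
from corridorscape.pipeline import SUMMER_MONTHS, WINTER_MONTHS, _write_paths_geojson
from corridorscape.raster import read_raster, write_raster


def main() -> None:
    CORRIDORS.mkdir(parents=True, exist_ok=True)
    ensembles = {
        m: read_raster(MODELS / f"ensemble_month_{m:02d}.asc") for m in range(1, 13)
    }
    thinned = read_occurrences(OCCURRENCES / "occurrences_thinned.csv")
    winter = grid_thin(thinned[thinned["month"].isin(WINTER_MONTHS)], CFG.thin_cell_deg)
    summer = grid_thin(thinned[thinned["month"].isin(SUMMER_MONTHS)], CFG.thin_cell_deg)
    print(f"{len(winter)} winter and {len(summer)} summer endpoint cells")
    for season in ("spring", "fall"):
        conductance = seasonal_conductance(ensembles, season, CFG.conductance_transform)
        graph = build_graph(conductance)
        paths, density, coords = lcp_density(graph, winter, summer)
        src_tab, gnd_tab = (winter, summer) if season == "spring" else (summer, winter)
        src = sorted({conductance.cell_of(lo, la)
                      for lo, la in zip(src_tab["lon"], src_tab["lat"])})
        gnd = sorted({conductance.cell_of(lo, la)
                      for lo, la in zip(gnd_tab["lon"], gnd_tab["lat"])})
        gnd_set = set(gnd)
        src = [c for c in src if c not in gnd_set]
        current = solve_current(conductance, src, gnd, injection=1.0)
        mask = percentile_mask(conductance, CFG.percentile_q)
        result = consensus_overlap(density, current, mask,
                                   CFG.percentile_q, CFG.percentile_q, paths)
        write_raster(CORRIDORS / f"conductance_{season}.asc", conductance)
        write_raster(CORRIDORS / f"lcp_density_{season}.asc", density)
        write_raster(CORRIDORS / f"current_{season}.asc", current)
        write_raster(CORRIDORS / f"consensus_{season}.asc", result.consensus)
        paths.to_csv(CORRIDORS / f"paths_{season}.csv", index=False)
        _write_paths_geojson(CORRIDORS / f"paths_{season}.geojson", paths, coords)
        n3 = int(result.consensus_cells().sum())
        print(f"{season}: {len(paths)} least-cost paths; "
              f"{n3} cells flagged by all three methods "
              f"(density >= {result.density_threshold:.0f} paths, "
              f"current >= {result.current_threshold:.4f} A)")


if __name__ == "__main__":
    main()
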