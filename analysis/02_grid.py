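#!/usr/bin/env python
"""Overlay the analysis grid and aggregate everything onto it.

Builds the 0.01 degree lattice over the region, assigns each cell the
municipality containing its centroid, disaggregates municipality covariates
equally over their cells, and counts OHCA events per cell.  Writes
results/cells.csv and results/grid.geojson.
"""

from _common import RESULTS, CELL_SIZE_DEG, load_municipalities, rebuild_grid

import pandas as pd

from aedplace import geoio
from aedplace.gridding import assign_municipality, count_events, disaggregate_covariates
from aedplace.synthetic import COVARIATE_COLUMNS


def main() -> None:
    municipalities = load_municipalities()
    grid = rebuild_grid(municipalities)
    cells = assign_municipality(grid, municipalities)
    covcols = [c for c in COVARIATE_COLUMNS if c in municipalities.columns]
    cells = disaggregate_covariates(municipalities, cells, covcols)
    events = pd.read_csv(RESULTS / "data" / "ohca.csv")
    y, outside = count_events(events, grid)
    cells["y"] = y
    ur = municipalities.set_index("municipality_id")["urban_rural"]
    cells["urban_rural"] = cells["municipality_id"].map(ur)

    geoio.write_points_csv(RESULTS / "cells.csv", cells)
    geoio.write_geojson(
        RESULTS / "grid.geojson",
        [grid.cell_polygon(c) for c in cells["cell_id"]],
        [{"cell_id": int(c), "y": int(v)} for c, v in zip(cells["cell_id"], cells["y"])],
    )

    modelled = cells["municipality_id"].notna().sum()
    print(f"grid: {grid.n_rows}x{grid.n_cols} cells of {CELL_SIZE_DEG} deg "
          f"({modelled} assigned to a municipality)")
    print(f"events on grid: {int(y.sum())} ({len(outside)} outside, reported not dropped)")
    print(f"cells with zero events: {(cells['y'] == 0).mean():.1%}")
    print(f"wrote {RESULTS / 'cells.csv'} and {RESULTS / 'grid.geojson'}")


if __name__ == "__main__":
    main()
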