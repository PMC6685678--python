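#!/usr/bin/env python
"""Build priority rankings and evaluate the chosen AED placements.

Ranks cells with predicted demand above 1 by lowest access then highest
predicted count, counts the newly placed AEDs per cell, and produces the
two evaluation tables: the top-20 priority areas with their new AED counts,
and the top-20 areas by AEDs received.  Writes the tables and a combined
GeoJSON for mapping under results/.
"""

import pandas as pd

from _common import RESULTS, PRED_THRESHOLD, TOP_K, load_municipalities, rebuild_grid, load_cells

from aedplace import geoio
from aedplace.priority import count_new_aeds, evaluation_tables, priority_rank


def main() -> None:
    municipalities = load_municipalities()
    grid = rebuild_grid(municipalities)
    cells = load_cells(grid)
    access = pd.read_csv(RESULTS / "access.csv")
    posterior = pd.read_csv(RESULTS / "posterior_cells.csv")
    selected = pd.read_csv(RESULTS / "selected_sites.csv")

    predicted = posterior[["cell_id"]].copy()
    predicted["predicted"] = posterior["pred_mean"]
    predicted = predicted.merge(cells[["cell_id", "urban_rural"]], on="cell_id", how="left")

    ranked = priority_rank(access, predicted, threshold=PRED_THRESHOLD)
    counts, n_outside = count_new_aeds(selected, grid, cell_ids=predicted["cell_id"].to_numpy())
    table_a, table_b = evaluation_tables(ranked, counts, top_k=TOP_K)

    geoio.write_points_csv(RESULTS / "priority.csv", ranked)
    geoio.write_points_csv(RESULTS / "priority_top.csv", table_a)
    geoio.write_points_csv(RESULTS / "aeds_added_top.csv", table_b)
    combined = access.merge(predicted, on="cell_id").merge(counts, on="cell_id")
    combined = combined.merge(ranked[["cell_id", "priority_rank"]], on="cell_id", how="left")
    import json

    geoio.write_geojson(
        RESULTS / "cells_combined.geojson",
        [grid.cell_polygon(c) for c in combined["cell_id"]],
        json.loads(combined.to_json(orient="records")),
    )

    print(f"{len(ranked)} cells with predicted OHCA count > {PRED_THRESHOLD:g}")
    in_top = (table_a["n_aeds_added"] > 0).sum()
    print(f"top {TOP_K} priority areas receiving at least one new AED: {in_top}")
    print(f"new AEDs outside the grid: {n_outside}")
    cols = ["priority_rank", "access", "predicted", "n_aeds_added", "urban_rural"]
    print("top 10 priority areas:")
    print(table_a[cols].head(10).to_string(index=False))
    print("top 10 areas by AEDs added:")
    print(table_b[cols].head(10).to_string(index=False))


if __name__ == "__main__":
    main()
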