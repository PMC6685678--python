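#!/usr/bin/env python
"""Compute two-step floating catchment access scores for every cell.

Step 1 gives every AED a supply-to-demand ratio against the model-predicted
demand at cell centroids within its 100 m catchment (exponential decay);
step 2 sums the ratios of the AEDs inside each cell.  Writes the per-AED
ratio table and the per-cell access scores under results/.
"""

import argparse

import pandas as pd

from _common import RESULTS, D0_M, load_municipalities, rebuild_grid, load_cells

from aedplace import geoio
from aedplace.access import DecayConfig, access_scores, aed_ratios


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--d0", type=float, default=D0_M)
    parser.add_argument("--kernel", choices=["exponential", "stepwise"],
                        default="exponential")
    args = parser.parse_args()

    municipalities = load_municipalities()
    grid = rebuild_grid(municipalities)
    cells = load_cells(grid)
    posterior = pd.read_csv(RESULTS / "posterior_cells.csv")
    aeds = pd.read_csv(RESULTS / "data" / "aeds.csv")

    merged = posterior.merge(
        cells[["cell_id", "centroid_lat", "centroid_lon"]], on="cell_id"
    )
    demand = pd.DataFrame({
        "cell_id": merged["cell_id"],
        "lat": merged["centroid_lat"],
        "lon": merged["centroid_lon"],
        "demand": merged["pred_mean"],
    })
    config = DecayConfig(d0=args.d0, kind=args.kernel)
    ratios = aed_ratios(aeds, demand, config)
    result = access_scores(ratios, grid, cell_ids=demand["cell_id"].to_numpy())

    geoio.write_points_csv(RESULTS / "aed_ratios.csv", result.ratios)
    geoio.write_points_csv(RESULTS / "access.csv", result.access)

    below1 = (result.access["access"] < 1).mean()
    print(f"{len(aeds)} AEDs, d0 = {args.d0:.0f} m, {args.kernel} decay")
    print(f"AEDs with empty catchment (flagged, R = 0): "
          f"{int(result.ratios['zero_demand'].sum())}")
    print(f"share of cells with access score < 1: {below1:.1%}")
    print(f"wrote {RESULTS / 'aed_ratios.csv'} and {RESULTS / 'access.csv'}")


if __name__ == "__main__":
    main()
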