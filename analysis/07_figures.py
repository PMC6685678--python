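#!/usr/bin/env python
"""Diagnostic and map figures from the finished analysis.

Observed versus posterior-mean counts with the line of perfect fit, the
access-score choropleth (cells with predicted demand below the threshold
greyed out), and the residual map.  PNGs land in results/figures/.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from _common import RESULTS, PRED_THRESHOLD, load_municipalities, rebuild_grid, load_cells


def main() -> None:
    municipalities = load_municipalities()
    grid = rebuild_grid(municipalities)
    cells = load_cells(grid)
    posterior = pd.read_csv(RESULTS / "posterior_cells.csv")
    access = pd.read_csv(RESULTS / "access.csv")
    outdir = RESULTS / "figures"
    outdir.mkdir(exist_ok=True)

    # observed vs fitted
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(posterior["pred_mean"], posterior["y"], s=8, alpha=0.5)
    lim = max(posterior["y"].max(), posterior["pred_mean"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="perfect fit")
    ax.set_xlabel("posterior mean predicted count")
    ax.set_ylabel("observed OHCA count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "observed_vs_predicted.png", dpi=150)

    # per-cell maps on the lattice
    merged = cells.merge(posterior, on="cell_id").merge(access, on="cell_id")
    for col, cmap, masked, name in (
        ("pred_mean", "viridis", False, "predicted_map"),
        ("residual", "coolwarm", False, "residual_map"),
        ("access", "viridis", True, "access_map"),
    ):
        img = np.full((grid.n_rows, grid.n_cols), np.nan)
        vals = merged[col].to_numpy(dtype=float)
        if masked:
            vals = np.where(merged["pred_mean"] > PRED_THRESHOLD, vals, np.nan)
        img[merged["row"], merged["col"]] = vals
        fig, ax = plt.subplots(figsize=(5.5, 5))
        im = ax.imshow(img, origin="lower", cmap=cmap)
        fig.colorbar(im, ax=ax, shrink=0.8, label=col)
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        fig.savefig(outdir / f"{name}.png", dpi=150)
    print(f"wrote 4 figures to {outdir}")


if __name__ == "__main__":
    main()
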