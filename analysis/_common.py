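"""Shared paths and helpers for the numbered analysis scripts.

All scripts read and write under ``results/`` at the repository root; stage
outputs are plain CSV/GeoJSON/JSON so every intermediate can be inspected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from aedplace import geoio
from aedplace.gridding import Grid, build_grid

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

#: study-wide analysis settings (the emulated case-study conditions)
CELL_SIZE_DEG = 0.01
D0_M = 100.0
RADIUS_M = 100.0
N_NEW_AEDS = 100
PRED_THRESHOLD = 1.0
TOP_K = 20
DEFAULT_SEED = 20190807  # deterministic default for the whole analysis


def load_municipalities() -> pd.DataFrame:
    """Municipality polygons merged with their covariate table."""
    geoms, props = geoio.read_geojson(DATA / "region.geojson")
    municipalities = props.copy()
    municipalities["geometry"] = geoms
    covariates = pd.read_csv(DATA / "covariates.csv")
    return municipalities.merge(
        covariates.drop(columns=["urban_rural"], errors="ignore"),
        on="municipality_id",
        how="left",
    )


def rebuild_grid(municipalities: pd.DataFrame) -> Grid:
    """Reconstruct the analysis grid from the region bounds (deterministic)."""
    bounds = np.array([g.bounds for g in municipalities["geometry"]])
    bbox = (
        bounds[:, 0].min(),
        bounds[:, 1].min(),
        bounds[:, 2].max(),
        bounds[:, 3].max(),
    )
    return build_grid(bbox, CELL_SIZE_DEG)


def load_cells(grid: Grid) -> pd.DataFrame:
    """The gridded cell table written by the gridding stage."""
    cells = pd.read_csv(RESULTS / "cells.csv")
    grid.cells = cells
    return cells
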