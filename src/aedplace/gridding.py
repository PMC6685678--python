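"""Fixed-resolution lon/lat gridding of a study region.

The analysis lattice is a rectangular grid of ``cell_size_deg`` × ``cell_size_deg``
degree cells anchored at the lower-left corner of the region bounding box.
Cell intervals are half-open, ``[x, x + size)`` in both axes, so every point in
the interior of the bounding box maps to exactly one cell and edge events have
a deterministic home.  Cells are identified by ``cell_id = row * n_cols + col``
with row 0 at the southern edge.

Municipality covariates observed at the (coarser) municipality scale are
disaggregated to cells by equal division: each cell whose centroid falls in a
municipality receives ``value / n_cells`` of every covariate, which conserves
municipality totals exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.strtree import STRtree


@dataclass
class Grid:
    """A rectangular lon/lat lattice over a bounding box.

    Attributes
    ----------
    min_lon, min_lat : float
        Lower-left corner (grid origin), degrees.
    cell_size : float
        Cell edge length in degrees (same in both axes).
    n_rows, n_cols : int
        Lattice dimensions; ``n_rows * n_cols`` cells tile the box.
    cells : pandas.DataFrame
        One row per cell: ``cell_id, row, col, centroid_lat, centroid_lon``,
        later augmented with ``municipality_id``, ``y`` and covariates.
    """

    min_lon: float
    min_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    cells: pd.DataFrame = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def point_to_cell(self, lat, lon) -> np.ndarray:
        """Map points to cell ids under the half-open rule; -1 if outside."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        col = np.floor((lon - self.min_lon) / self.cell_size).astype(int)
        row = np.floor((lat - self.min_lat) / self.cell_size).astype(int)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.where(inside, row * self.n_cols + col, -1)
        return out

    def cell_polygon(self, cell_id: int):
        """Shapely box for one cell."""
        row, col = divmod(int(cell_id), self.n_cols)
        x0 = self.min_lon + col * self.cell_size
        y0 = self.min_lat + row * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)


def build_grid(bbox: tuple[float, float, float, float], cell_size_deg: float) -> Grid:
    """Tile a bounding box with half-open degree cells.

    Parameters
    ----------
    bbox : (min_lon, min_lat, max_lon, max_lat)
        Region bounds in degrees (shapely ``bounds`` order).
    cell_size_deg : float
        Cell edge in degrees; at mid-latitudes 0.01° is roughly a 1.1 km cell.

    Returns
    -------
    Grid
        ``ceil(Δlon/size) × ceil(Δlat/size)`` cells covering the box.
    """
    min_lon, min_lat, max_lon, max_lat = map(float, bbox)
    if not (max_lon > min_lon and max_lat > min_lat):
        raise ValueError(f"degenerate or inverted bbox: {bbox}")
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    # half-open cover: the last cell may overhang the box, never undershoot
    n_cols = math.ceil((max_lon - min_lon) / cell_size_deg - 1e-12)
    n_rows = math.ceil((max_lat - min_lat) / cell_size_deg - 1e-12)
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_rows * n_cols),
            "row": rows,
            "col": cols,
            "centroid_lat": min_lat + (rows + 0.5) * cell_size_deg,
            "centroid_lon": min_lon + (cols + 0.5) * cell_size_deg,
        }
    )
    return Grid(min_lon, min_lat, cell_size_deg, n_rows, n_cols, cells)


def assign_municipality(grid: Grid, municipalities: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell the municipality whose polygon covers its centroid.

    ``municipalities`` needs columns ``municipality_id`` and ``geometry``
    (shapely polygons).  Cells whose centroid falls outside every polygon get
    a missing ``municipality_id`` and are excluded from modelling downstream.
    A centroid covered by two or more polygons is an input error (polygons
    should partition the region) and raises, naming the offenders.

    Returns the grid's cell table with ``municipality_id`` added, and updates
    ``municipalities['n_cells']`` in place.
    """
    geoms = list(municipalities["geometry"])
    tree = STRtree(geoms)
    cells = grid.cells
    assigned = np.full(len(cells), -1, dtype=int)
    for idx, (lat, lon) in enumerate(zip(cells["centroid_lat"], cells["centroid_lon"])):
        pt = Point(lon, lat)
        hits = [g for g in tree.query(pt) if geoms[g].covers(pt)]
        if len(hits) > 1:
            offenders = municipalities["municipality_id"].iloc[hits].tolist()
            raise ValueError(
                f"cell {cells['cell_id'].iloc[idx]} centroid covered by "
                f"multiple municipalities: {offenders}"
            )
        if hits:
            assigned[idx] = municipalities["municipality_id"].iloc[hits[0]]
    out = cells.copy()
    out["municipality_id"] = pd.array(
        [a if a >= 0 else None for a in assigned], dtype="Int64"
    )
    counts = out["municipality_id"].value_counts()
    municipalities["n_cells"] = (
        municipalities["municipality_id"].map(counts).fillna(0).astype(int)
    )
    grid.cells = out
    return out


def disaggregate_covariates(
    municipalities: pd.DataFrame,
    cells: pd.DataFrame,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Divide municipality covariates equally among their cells.

    A municipality containing ``n`` cell centroids contributes ``value / n``
    of each covariate to every one of those cells, so the sum over its cells
    reproduces the municipality value exactly.  Unassigned cells get NaN.
    """
    if covariate_cols is None:
        covariate_cols = [
            c
            for c in municipalities.columns
            if c not in ("municipality_id", "geometry", "urban_rural", "n_cells")
        ]
    if (municipalities.loc[municipalities["n_cells"] == 0].shape[0]) and municipalities[
        "n_cells"
    ].min() < 0:
        raise ValueError("negative n_cells")
    muni = municipalities.set_index("municipality_id")
    out = cells.copy()
    for col in covariate_cols:
        per_cell = muni[col] / muni["n_cells"].replace(0, np.nan)
        out[col] = out["municipality_id"].map(per_cell).astype(float)
    return out


def count_events(events: pd.DataFrame, grid: Grid) -> tuple[np.ndarray, pd.DataFrame]:
    """Count events per grid cell.

    Parameters
    ----------
    events : DataFrame with ``lat``/``lon`` columns.
    grid : Grid

    Returns
    -------
    y : int array of length ``grid.n_cells`` (event counts per cell)
    outside : the rows of ``events`` that fall outside the grid (reported,
        never silently dropped): ``sum(y) + len(outside) == len(events)``.

    Raises
    ------
    ValueError
        If any row has a malformed coordinate (NaN or latitude outside
        [-90, 90]); the message lists the offending row indices.
    """
    lat = pd.to_numeric(events["lat"], errors="coerce")
    lon = pd.to_numeric(events["lon"], errors="coerce")
    bad = lat.isna() | lon.isna() | (lat.abs() > 90)
    if bad.any():
        raise ValueError(f"malformed coordinates in event rows: {list(events.index[bad])}")
    cell = grid.point_to_cell(lat.to_numpy(), lon.to_numpy())
    y = np.bincount(cell[cell >= 0], minlength=grid.n_cells)
    outside = events.loc[cell < 0]
    return y, outside


def build_adjacency(
    grid: Grid,
    contiguity: str = "rook",
    cell_ids: np.ndarray | None = None,
) -> dict[int, list[int]]:
    """Lattice contiguity neighbour lists.

    Rook contiguity (default) links cells sharing an edge (up to 4
    neighbours); queen also links diagonal cells (up to 8).  If ``cell_ids``
    is given, the adjacency is restricted to that subset of cells (links to
    excluded cells are dropped).
    """
    if contiguity == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif contiguity == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError(f"unknown contiguity {contiguity!r} (use 'rook' or 'queen')")
    if cell_ids is None:
        keep = set(range(grid.n_cells))
    else:
        keep = set(int(c) for c in cell_ids)
    adj: dict[int, list[int]] = {}
    for cid in sorted(keep):
        row, col = divmod(cid, grid.n_cols)
        nbrs = []
        for dr, dc in offsets:
            r, c = row + dr, col + dc
            if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols:
                nid = r * grid.n_cols + c
                if nid in keep:
                    nbrs.append(nid)
        adj[cid] = sorted(nbrs)
    return adj
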