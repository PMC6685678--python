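"""Enhanced two-step floating catchment area (2SFCA) access scores.

Step 1: each AED ``j`` (supply ``S_j``, normally 1) gets a supply-to-demand
ratio ``R_j = S_j / sum_k D_k G(d_kj, d0)`` where the sum runs over demand
points within the catchment radius ``d0`` and ``G`` is a distance-decay
kernel.  Step 2: each grid cell's access score ``A_i`` is the sum of ``R_j``
over the AEDs located inside it.

Demand points are grid-cell centroids carrying the model's posterior-mean
predicted OHCA count.  Note the scale mismatch this implies: with the default
``d0`` of 100 m and ~1.1 km cells, an AED's catchment rarely contains more
than the centroid of its own cell — see the methods note for the
consequences and the supported alternatives.

The default kernel is the truncated-Gaussian exponential decay

    G(d, d0) = (exp(-(d/d0)^2 / 2) - exp(-1/2)) / (1 - exp(-1/2)),  d <= d0
             = 0,                                                   d >  d0

which is 1 at d=0, falls continuously and strictly to 0 at d=d0, and is 0
beyond.  A piecewise-constant stepwise kernel is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aedplace.coverage import haversine_matrix
from aedplace.gridding import Grid

_HALF = np.exp(-0.5)


@dataclass
class DecayConfig:
    """Catchment radius and decay-kernel choice.

    ``d0`` is the catchment radius in metres (100 by default; 250 is the
    supported sensitivity value).  ``kind`` selects the exponential
    (truncated-Gaussian) kernel or a stepwise kernel defined by
    ``step_breaks``: a list of ``(radius_m, weight)`` pairs with
    nonincreasing weights in [0, 1]; a point at distance d gets the weight of
    the first break with ``d <= radius``.  The default single step
    ``[(d0, 1.0)]`` is plain binary coverage.
    """

    d0: float = 100.0
    kind: str = "exponential"
    step_breaks: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.kind not in ("exponential", "stepwise"):
            raise ValueError("kind must be 'exponential' or 'stepwise'")
        if self.kind == "stepwise":
            if self.step_breaks is None:
                self.step_breaks = [(self.d0, 1.0)]
            radii = [r for r, _ in self.step_breaks]
            weights = [w for _, w in self.step_breaks]
            if sorted(radii) != radii or any(r <= 0 for r in radii):
                raise ValueError("step radii must be positive and increasing")
            if any(not 0 <= w <= 1 for w in weights) or sorted(
                weights, reverse=True
            ) != weights:
                raise ValueError("step weights must be nonincreasing within [0, 1]")


def decay_weight(d, config: DecayConfig) -> np.ndarray:
    """Distance-decay weight ``G(d, d0)`` in [0, 1] (vectorised over d)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if config.kind == "exponential":
        g = (np.exp(-0.5 * (d / config.d0) ** 2) - _HALF) / (1.0 - _HALF)
        return np.where(d <= config.d0, g, 0.0)
    w = np.zeros(d.shape)
    for radius, weight in reversed(config.step_breaks):
        w = np.where(d <= radius, weight, w)
    return w


@dataclass
class AccessResult:
    """Per-AED ratios and per-cell access scores."""

    ratios: pd.DataFrame = field(repr=False)  # aed_id, R, zero_demand, cell_id
    access: pd.DataFrame = field(repr=False)  # cell_id, access
    n_outside_grid: int = 0

    @property
    def total_ratio(self) -> float:
        """Sum of R_j over in-grid AEDs (equals the sum of access scores)."""
        return float(self.ratios.loc[self.ratios["cell_id"] >= 0, "R"].sum())


def supply_demand_ratio(
    aed: pd.Series | dict,
    demand: pd.DataFrame,
    config: DecayConfig | None = None,
) -> tuple[float, bool]:
    """Step 1 for a single AED: ``R_j`` and the zero-demand flag.

    ``aed`` needs ``lat``/``lon`` (and optionally ``supply``, default 1);
    ``demand`` needs ``lat``, ``lon`` and ``demand`` columns.  If no demand
    point with positive weighted demand lies within ``d0``, the ratio is set
    to 0 and flagged rather than left undefined.
    """
    config = config or DecayConfig()
    d = haversine_matrix(
        np.array([[aed["lat"], aed["lon"]]]),
        demand[["lat", "lon"]].to_numpy(dtype=float),
    )[0]
    weighted = demand["demand"].to_numpy(dtype=float) * decay_weight(d, config)
    total = float(weighted.sum())
    supply = float(aed.get("supply", 1.0) if isinstance(aed, dict) else aed.get("supply", 1.0))
    if total <= 0:
        return 0.0, True
    return supply / total, False


def aed_ratios(
    aeds: pd.DataFrame,
    demand: pd.DataFrame,
    config: DecayConfig | None = None,
    public_only: bool = False,
) -> pd.DataFrame:
    """Step 1 for all AEDs at once.

    Returns a DataFrame ``(aed_id, lat, lon, R, zero_demand)``.  With
    ``public_only`` the supply of time-limited AEDs is set to zero (they keep
    a row, with R = 0), restricting access to 24/7 public devices.
    """
    config = config or DecayConfig()
    out = aeds[["aed_id", "lat", "lon"]].copy()
    supply = aeds["supply"].to_numpy(dtype=float) if "supply" in aeds else np.ones(len(aeds))
    if public_only and "availability" in aeds:
        supply = np.where(aeds["availability"] == "public_24_7", supply, 0.0)
    d = haversine_matrix(
        aeds[["lat", "lon"]].to_numpy(dtype=float),
        demand[["lat", "lon"]].to_numpy(dtype=float),
    )
    weighted = decay_weight(d, config) * demand["demand"].to_numpy(dtype=float)
    total = weighted.sum(axis=1)
    zero = total <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(zero, 0.0, supply / np.where(zero, 1.0, total))
    out["R"] = R
    out["zero_demand"] = zero
    return out


def access_scores(ratios: pd.DataFrame, grid: Grid, cell_ids=None) -> AccessResult:
    """Step 2: sum each cell's AED ratios into its access score ``A_i``.

    AEDs are assigned to cells by the grid's half-open point-in-cell rule;
    AEDs outside the grid are excluded and counted in ``n_outside_grid``.
    ``cell_ids`` restricts the output table to given cells (default: all
    grid cells); cells without an AED score 0.
    """
    ratios = ratios.copy()
    ratios["cell_id"] = grid.point_to_cell(
        ratios["lat"].to_numpy(), ratios["lon"].to_numpy()
    )
    inside = ratios["cell_id"] >= 0
    sums = ratios.loc[inside].groupby("cell_id")["R"].sum()
    if cell_ids is None:
        cell_ids = np.arange(grid.n_cells)
    access = pd.DataFrame({"cell_id": np.asarray(cell_ids)})
    access["access"] = access["cell_id"].map(sums).fillna(0.0)
    return AccessResult(
        ratios=ratios, access=access, n_outside_grid=int((~inside).sum())
    )
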