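"""Priority ranking of areas and evaluation of a placement solution.

Cells with a model-predicted OHCA count above a threshold (default 1) are
ranked by lowest access score first, ties broken by highest predicted count,
then by cell id for full determinism.  A placement solution is evaluated by
counting how many of the newly chosen AED sites fall in each priority area,
yielding the two evaluation tables: the top-k priority areas with their new
AED counts, and the top-k areas by number of AEDs added.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from aedplace.gridding import Grid


def priority_rank(
    access: pd.DataFrame,
    predicted: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Rank cells by (ascending access, descending predicted demand).

    Parameters
    ----------
    access : DataFrame with ``cell_id`` and ``access``.
    predicted : DataFrame with ``cell_id`` and ``predicted`` (posterior-mean
        predicted OHCA count).
    threshold : cells with ``predicted <= threshold`` are excluded (the
        ranking only considers areas with meaningful expected demand).

    Returns a DataFrame ``(priority_rank, cell_id, access, predicted, ...)``
    with ranks 1..K and no gaps; extra columns of ``predicted`` (e.g. an
    ``urban_rural`` label) are carried through.
    """
    merged = access.merge(predicted, on="cell_id", how="inner")
    if "predicted" not in merged or "access" not in merged:
        raise ValueError("need 'access' and 'predicted' columns")
    kept = merged.loc[merged["predicted"] > threshold].copy()
    kept = kept.sort_values(
        by=["access", "predicted", "cell_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    kept.insert(0, "priority_rank", np.arange(1, len(kept) + 1))
    return kept


def count_new_aeds(
    selected_sites: pd.DataFrame, grid: Grid, cell_ids=None
) -> tuple[pd.DataFrame, int]:
    """Count selected new AED sites per grid cell (point-in-cell).

    Returns ``(counts, n_outside)`` where ``counts`` has ``cell_id`` and
    ``n_aeds_added`` for every requested cell (default: all grid cells) and
    ``n_outside`` is the number of selected sites falling outside the grid,
    so ``sum(n_aeds_added) + n_outside == len(selected_sites)``.
    """
    cell = grid.point_to_cell(
        selected_sites["lat"].to_numpy(), selected_sites["lon"].to_numpy()
    )
    inside = cell >= 0
    counts = pd.Series(cell[inside]).value_counts()
    if cell_ids is None:
        cell_ids = np.arange(grid.n_cells)
    out = pd.DataFrame({"cell_id": np.asarray(cell_ids)})
    out["n_aeds_added"] = out["cell_id"].map(counts).fillna(0).astype(int)
    return out, int((~inside).sum())


def evaluation_tables(
    ranked: pd.DataFrame,
    counts: pd.DataFrame,
    top_k: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two placement-evaluation tables.

    Table A: the ``top_k`` best priority ranks with their new-AED counts —
    does the optimiser serve the least accessible, highest-demand areas?
    Table B: the ``top_k`` ranked areas receiving the most new AEDs
    (descending ``n_aeds_added``, ties broken by better priority rank) —
    where does the optimiser actually put devices?
    """
    joined = ranked.merge(counts, on="cell_id", how="left")
    joined["n_aeds_added"] = joined["n_aeds_added"].fillna(0).astype(int)
    if len(joined) < top_k:
        warnings.warn(
            f"only {len(joined)} ranked cells available for top_k={top_k}",
            stacklevel=2,
        )
    table_a = joined.nsmallest(top_k, "priority_rank", keep="all").head(top_k)
    table_b = (
        joined.sort_values(
            by=["n_aeds_added", "priority_rank"],
            ascending=[False, True],
            kind="mergesort",
        )
        .head(top_k)
        .reset_index(drop=True)
    )
    return table_a.reset_index(drop=True), table_b
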