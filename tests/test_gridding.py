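import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from aedplace.gridding import (
    assign_municipality,
    build_adjacency,
    build_grid,
    count_events,
    disaggregate_covariates,
)


class TestBuildGrid:
    @pytest.mark.parametrize(
        "bbox, expected",
        [
            ((0.0, 0.0, 0.03, 0.02), 6),  # 3 cols x 2 rows
            ((0.0, 0.0, 0.01, 0.01), 1),  # exactly one cell
            ((0.0, 0.0, 0.025, 0.015), 6),  # partial cells round up
        ],
    )
    def test_cell_count(self, bbox, expected):
        assert build_grid(bbox, 0.01).n_cells == expected

    def test_inverted_bbox_rejected(self):
        with pytest.raises(ValueError, match="bbox"):
            build_grid((0.0, 0.0, -0.01, 0.02), 0.01)
        with pytest.raises(ValueError, match="positive"):
            build_grid((0.0, 0.0, 0.03, 0.02), 0.0)

    @given(
        lat=st.floats(min_value=0.0, max_value=0.049999, allow_nan=False),
        lon=st.floats(min_value=0.0, max_value=0.049999, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_every_interior_point_maps_to_one_cell(self, lat, lon):
        grid = build_grid((0.0, 0.0, 0.05, 0.05), 0.01)
        cid = int(grid.point_to_cell(lat, lon))
        assert 0 <= cid < grid.n_cells
        # containment under the half-open rule
        row, col = divmod(cid, grid.n_cols)
        assert col * 0.01 <= lon < (col + 1) * 0.01 + 1e-9
        assert row * 0.01 <= lat < (row + 1) * 0.01 + 1e-9

    def test_edge_point_belongs_to_upper_cell(self, grid_5x5):
        # a point on a shared cell edge goes to the cell whose half-open
        # interval starts there
        cid = int(grid_5x5.point_to_cell(0.0, 0.01))
        assert cid == 1


class TestAssignMunicipality:
    def test_centroid_in_polygon(self, grid_5x5):
        munis = pd.DataFrame(
            {
                "municipality_id": [1, 2],
                "geometry": [box(0, 0, 0.05, 0.03), box(0, 0.03, 0.05, 0.05)],
            }
        )
        cells = assign_municipality(grid_5x5, munis)
        assert (cells.loc[cells["centroid_lat"] < 0.03, "municipality_id"] == 1).all()
        assert (cells.loc[cells["centroid_lat"] > 0.03, "municipality_id"] == 2).all()
        assert munis.loc[0, "n_cells"] == 15 and munis.loc[1, "n_cells"] == 10

    def test_outside_all_polygons_is_missing(self, grid_5x5):
        munis = pd.DataFrame(
            {"municipality_id": [1], "geometry": [box(0, 0, 0.05, 0.03)]}
        )
        cells = assign_municipality(grid_5x5, munis)
        assert cells["municipality_id"].isna().sum() == 10

    def test_overlapping_polygons_rejected(self, grid_5x5):
        munis = pd.DataFrame(
            {
                "municipality_id": [1, 2],
                "geometry": [box(0, 0, 0.05, 0.05), box(0, 0, 0.02, 0.02)],
            }
        )
        with pytest.raises(ValueError, match="multiple municipalities"):
            assign_municipality(grid_5x5, munis)


class TestDisaggregateCovariates:
    def test_equal_division_and_conservation(self, grid_5x5):
        munis = pd.DataFrame(
            {
                "municipality_id": [1, 2],
                "geometry": [box(0, 0, 0.05, 0.02), box(0, 0.02, 0.05, 0.05)],
                "pop_density": [10.0, 7.5],
                "prop_male": [0.5, 0.45],
            }
        )
        cells = assign_municipality(grid_5x5, munis)
        cells = disaggregate_covariates(munis, cells, ["pop_density", "prop_male"])
        first = cells.loc[cells["municipality_id"] == 1]
        # municipality value 10 split over 10 cells -> 1 each
        assert np.allclose(first["pop_density"], 1.0)
        for col in ("pop_density", "prop_male"):
            sums = cells.groupby("municipality_id")[col].sum()
            for mid, total in zip(munis["municipality_id"], munis[col]):
                assert abs(sums[mid] - total) <= 1e-12 * abs(total)

    def test_single_cell_keeps_value(self):
        grid = build_grid((0.0, 0.0, 0.01, 0.01), 0.01)
        munis = pd.DataFrame(
            {
                "municipality_id": [1],
                "geometry": [box(0, 0, 0.01, 0.01)],
                "pop_density": [42.0],
            }
        )
        cells = assign_municipality(grid, munis)
        cells = disaggregate_covariates(munis, cells, ["pop_density"])
        assert cells["pop_density"].iloc[0] == 42.0


class TestCountEvents:
    def test_no_events(self, grid_5x5):
        y, outside = count_events(pd.DataFrame({"lat": [], "lon": []}), grid_5x5)
        assert y.sum() == 0 and len(outside) == 0

    def test_clustered_events_and_conservation(self, grid_5x5):
        events = pd.DataFrame(
            {"lat": [0.005] * 5 + [0.5], "lon": [0.005] * 5 + [0.5]}
        )
        y, outside = count_events(events, grid_5x5)
        assert y[0] == 5 and y.sum() == 5
        assert len(outside) == 1
        assert y.sum() + len(outside) == len(events)

    def test_edge_event_assigned_once(self, grid_5x5):
        y, outside = count_events(pd.DataFrame({"lat": [0.0], "lon": [0.01]}), grid_5x5)
        assert y.sum() == 1 and y[1] == 1  # the half-open rule puts it in cell 1

    def test_malformed_coordinates_reported_by_row(self, grid_5x5):
        events = pd.DataFrame({"lat": [0.005, 95.0], "lon": [0.005, 0.005]})
        with pytest.raises(ValueError, match=r"rows: \[1\]"):
            count_events(events, grid_5x5)


class TestAdjacency:
    def test_rook_neighbour_counts(self, grid_5x5):
        adj = build_adjacency(grid_5x5, "rook")
        assert len(adj[12]) == 4  # interior
        assert len(adj[0]) == 2  # corner
        assert len(adj[2]) == 3  # edge

    def test_queen_interior_has_eight(self, grid_5x5):
        adj = build_adjacency(grid_5x5, "queen")
        assert len(adj[12]) == 8

    def test_symmetry_and_no_self_loops(self, grid_5x5):
        for contiguity in ("rook", "queen"):
            adj = build_adjacency(grid_5x5, contiguity)
            for i, nbrs in adj.items():
                assert i not in nbrs
                for j in nbrs:
                    assert i in adj[j]

    def test_subset_restriction_drops_links(self, grid_5x5):
        keep = [0, 1, 2, 12]
        adj = build_adjacency(grid_5x5, "rook", cell_ids=keep)
        assert set(adj) == set(keep)
        assert adj[12] == []  # its lattice neighbours are excluded
        assert adj[1] == [0, 2]
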