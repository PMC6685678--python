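"""End-to-end pipeline: grid → model → access → optimise → rank.

One :class:`PipelineConfig` (flat YAML key-value file or constructed in
code) drives the whole analysis.  Every stage writes plain-text outputs
(CSV/GeoJSON/JSON) into the run directory, and a manifest records the
configuration hash, seeds and per-stage row counts, so a run is fully
re-creatable from its manifest.  With fixed seeds the outputs are
byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aedplace import geoio
from aedplace.access import DecayConfig, access_scores, aed_ratios
from aedplace.coverage import (
    CoverageProblem,
    build_coverage_matrix,
    dedupe_candidates,
    greedy_mclp,
    remove_covered,
    solve_mclp,
)
from aedplace.gridding import (
    assign_municipality,
    build_adjacency,
    build_grid,
    count_events,
    disaggregate_covariates,
)
from aedplace.model import ZipCarPriorSpec, fit, morans_i
from aedplace.priority import count_new_aeds, evaluation_tables, priority_rank
from aedplace.synthetic import COVARIATE_COLUMNS, SyntheticDataset


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name and code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class PipelineConfig:
    """All paths, parameters and seeds of one pipeline run."""

    region: str = "region.geojson"
    events: str = "ohca.csv"
    covariates: str = "covariates.csv"
    aeds: str = "aeds.csv"
    buildings: str = "buildings.csv"
    out_dir: str = "run"
    cell_size_deg: float = 0.01
    contiguity: str = "rook"
    d0: float = 100.0
    kernel: str = "exponential"
    radius: float = 100.0
    n_new: int = 100
    threshold: float = 1.0
    top_k: int = 20
    draws: int = 1000
    warmup: int = 1000
    solver: str = "exact"
    public_only: bool = False
    n_permutations: int = 999
    seed_sampler: int = 1
    seed_permutation: int = 2

    def __post_init__(self) -> None:
        for name in ("cell_size_deg", "d0", "radius", "threshold"):
            if getattr(self, name) is not None and getattr(self, name) <= 0 and name != "threshold":
                raise ValueError(f"{name} must be positive")
        if self.n_new < 0 or self.draws < 1 or self.warmup < 0:
            raise ValueError("n_new, draws and warmup must be sensible")
        if self.solver not in ("exact", "greedy"):
            raise ValueError("solver must be 'exact' or 'greedy'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def write_synthetic_bundle(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Write a synthetic dataset as the pipeline's five input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    muni = dataset.municipalities
    geoio.write_geojson(
        out / "region.geojson",
        list(muni["geometry"]),
        [
            {"municipality_id": int(m), "urban_rural": str(u)}
            for m, u in zip(muni["municipality_id"], muni["urban_rural"])
        ],
    )
    covcols = ["municipality_id"] + COVARIATE_COLUMNS + ["urban_rural"]
    geoio.write_points_csv(out / "covariates.csv", muni[covcols])
    geoio.write_points_csv(out / "ohca.csv", dataset.events[["id", "lat", "lon"]])
    geoio.write_points_csv(
        out / "aeds.csv", dataset.aeds[["aed_id", "lat", "lon", "availability", "supply"]]
    )
    geoio.write_points_csv(out / "buildings.csv", dataset.buildings)
    return {
        "region": str(out / "region.geojson"),
        "events": str(out / "ohca.csv"),
        "covariates": str(out / "covariates.csv"),
        "aeds": str(out / "aeds.csv"),
        "buildings": str(out / "buildings.csv"),
    }


def validate_inputs(paths: dict[str, str]) -> dict[str, dict]:
    """Report-only validation of the input files.

    For each path: parse status, row count, coordinate-range violations and
    duplicate ids.  Never raises — problems land in the report.
    """
    report: dict[str, dict] = {}
    id_cols = {"events": "id", "aeds": "aed_id", "buildings": "site_id"}
    for name, path in paths.items():
        entry: dict = {"path": str(path), "exists": Path(path).exists()}
        if not entry["exists"]:
            entry["status"] = "missing"
            report[name] = entry
            continue
        try:
            if str(path).endswith(".geojson") or str(path).endswith(".json"):
                geoms, props = geoio.read_geojson(path)
                entry["n_rows"] = len(geoms)
                if "municipality_id" in props:
                    dup = props["municipality_id"].duplicated()
                    entry["duplicate_ids"] = props.loc[dup, "municipality_id"].tolist()
            else:
                df = pd.read_csv(path)
                entry["n_rows"] = len(df)
                if {"lat", "lon"} <= set(df.columns):
                    lat = pd.to_numeric(df["lat"], errors="coerce")
                    lon = pd.to_numeric(df["lon"], errors="coerce")
                    bad = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 360)
                    entry["bad_coordinate_rows"] = df.index[bad].tolist()
                idc = id_cols.get(name)
                if idc and idc in df.columns:
                    entry["duplicate_ids"] = df.loc[df[idc].duplicated(), idc].tolist()
            entry["status"] = "ok"
            if entry.get("bad_coordinate_rows") or entry.get("duplicate_ids"):
                entry["status"] = "flagged"
        except Exception as exc:  # report, don't raise
            entry["status"] = "parse-error"
            entry["error"] = str(exc)
        report[name] = entry
    return report


def _read_inputs(config: PipelineConfig):
    for stage, attr in (
        ("grid", "region"),
        ("grid", "events"),
        ("grid", "covariates"),
        ("access", "aeds"),
        ("optimize", "buildings"),
    ):
        path = getattr(config, attr)
        if not Path(path).exists():
            raise PipelineError(stage, "missing-file", f"input file not found: {path}")
    geoms, props = geoio.read_geojson(config.region)
    municipalities = props.copy()
    municipalities["geometry"] = geoms
    covariates = pd.read_csv(config.covariates)
    municipalities = municipalities.merge(
        covariates.drop(columns=["urban_rural"], errors="ignore"),
        on="municipality_id",
        how="left",
    )
    events = geoio.read_points_csv(config.events)
    aeds = geoio.read_points_csv(config.aeds)
    buildings = geoio.read_points_csv(config.buildings)
    return municipalities, events, aeds, buildings


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write all outputs plus a manifest.

    Returns the manifest dict.  Raises :class:`PipelineError` naming the
    failing stage on any error.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    municipalities, events, aeds, buildings = _read_inputs(config)

    # ---- stage: grid ----
    try:
        bounds = np.array([g.bounds for g in municipalities["geometry"]])
        bbox = (bounds[:, 0].min(), bounds[:, 1].min(), bounds[:, 2].max(), bounds[:, 3].max())
        grid = build_grid(bbox, config.cell_size_deg)
        cells = assign_municipality(grid, municipalities)
        covcols = [c for c in COVARIATE_COLUMNS if c in municipalities.columns]
        cells = disaggregate_covariates(municipalities, cells, covcols)
        y, outside = count_events(events, grid)
        cells["y"] = y
        if "urban_rural" in municipalities.columns:
            ur = municipalities.set_index("municipality_id")["urban_rural"]
            cells["urban_rural"] = cells["municipality_id"].map(ur)
        grid.cells = cells
        geoio.write_points_csv(out / "cells.csv", cells)
        manifest["stages"]["grid"] = {
            "n_cells": int(grid.n_cells),
            "n_modelled": int(cells["municipality_id"].notna().sum()),
            "n_events": int(len(events)),
            "n_events_outside_grid": int(len(outside)),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("grid", "stage-failure", str(exc)) from exc

    # ---- stage: fit ----
    try:
        modelled = cells.loc[cells["municipality_id"].notna()].copy()
        adjacency = build_adjacency(
            grid, config.contiguity, cell_ids=modelled["cell_id"].to_numpy()
        )
        posterior = fit(
            modelled,
            adjacency,
            prior=ZipCarPriorSpec(),
            covariate_cols=covcols,
            draws=config.draws,
            warmup=config.warmup,
            seed=config.seed_sampler,
        )
        summary = posterior.cell_summary()
        geoio.write_points_csv(out / "posterior_cells.csv", summary)
        geoio.write_points_csv(out / "coefficients.csv", posterior.coef_table())
        I, pval = morans_i(
            posterior.residual,
            adjacency,
            n_permutations=config.n_permutations,
            seed=config.seed_permutation,
        )
        diagnostics = {
            "rhat": posterior.rhat,
            "converged": bool(posterior.converged),
            "acceptance": posterior.acceptance,
            "morans_i": I,
            "morans_i_pvalue": pval,
        }
        (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
        manifest["stages"]["fit"] = {
            "n_cells": int(len(modelled)),
            "converged": bool(posterior.converged),
            "morans_i": I,
        }
        if not posterior.converged:
            manifest["stages"]["fit"]["warning"] = "split-Rhat >= 1.05 on some parameter"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit", "stage-failure", str(exc)) from exc

    # ---- stage: access ----
    try:
        decay = DecayConfig(d0=config.d0, kind=config.kernel)
        demand = pd.DataFrame(
            {
                "cell_id": posterior.cell_ids,
                "lat": modelled.set_index("cell_id").loc[posterior.cell_ids, "centroid_lat"].to_numpy(),
                "lon": modelled.set_index("cell_id").loc[posterior.cell_ids, "centroid_lon"].to_numpy(),
                "demand": posterior.pred_mean,
            }
        )
        ratios = aed_ratios(aeds, demand, decay, public_only=config.public_only)
        result = access_scores(ratios, grid, cell_ids=posterior.cell_ids)
        geoio.write_points_csv(out / "aed_ratios.csv", result.ratios)
        geoio.write_points_csv(out / "access.csv", result.access)
        manifest["stages"]["access"] = {
            "n_aeds": int(len(aeds)),
            "n_aeds_outside_grid": result.n_outside_grid,
            "n_zero_demand_aeds": int(result.ratios["zero_demand"].sum()),
            "share_access_below_1": float((result.access["access"] < 1).mean()),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("access", "stage-failure", str(exc)) from exc

    # ---- stage: optimize ----
    try:
        uncovered, n_removed = remove_covered(events, aeds, config.radius)
        sites = dedupe_candidates(buildings).reset_index(drop=True)
        a = build_coverage_matrix(uncovered, sites, config.radius)
        n_new = min(config.n_new, len(sites))
        problem = CoverageProblem(
            a=a,
            ohca_ids=uncovered["id"].to_numpy(),
            site_ids=sites["site_id"].to_numpy(),
            radius=config.radius,
            N=n_new,
        )
        solver = solve_mclp if config.solver == "exact" else greedy_mclp
        solution = solver(problem)
        sel = sites.set_index("site_id").loc[solution.selected].reset_index()
        # rank selected sites by marginal coverage (greedy replay order)
        marg = []
        covered_mask = np.zeros(len(uncovered), dtype=bool)
        cols = {sid: k for k, sid in enumerate(problem.site_ids)}
        remaining = list(solution.selected)
        order = []
        while remaining:
            gains = [
                (int((a[:, cols[s]] & ~covered_mask).sum()), s) for s in sorted(remaining)
            ]
            g, s = max(gains, key=lambda t: t[0])  # first max: lowest id on ties
            order.append(s)
            marg.append(g)
            covered_mask |= a[:, cols[s]]
            remaining.remove(s)
        sel = sel.set_index("site_id").loc[order].reset_index()
        sel["rank_by_marginal_coverage"] = np.arange(1, len(sel) + 1)
        sel["marginal_coverage"] = marg
        geoio.write_points_csv(out / "selected_sites.csv", sel)
        report = {
            "n_ohca": int(len(events)),
            "n_removed_already_covered": int(n_removed),
            "n_uncovered": int(len(uncovered)),
            "n_candidates": int(len(sites)),
            "budget": int(n_new),
            "objective": int(solution.objective),
            "optimal": bool(solution.optimal),
        }
        (out / "coverage_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"]["optimize"] = report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("optimize", "stage-failure", str(exc)) from exc

    # ---- stage: rank ----
    try:
        predicted = pd.DataFrame(
            {"cell_id": posterior.cell_ids, "predicted": posterior.pred_mean}
        )
        if "urban_rural" in cells.columns:
            predicted = predicted.merge(
                cells[["cell_id", "urban_rural"]], on="cell_id", how="left"
            )
        ranked = priority_rank(result.access, predicted, threshold=config.threshold)
        counts, n_out = count_new_aeds(sel, grid, cell_ids=posterior.cell_ids)
        table_a, table_b = evaluation_tables(ranked, counts, top_k=config.top_k)
        geoio.write_points_csv(out / "priority.csv", ranked)
        geoio.write_points_csv(out / "priority_top.csv", table_a)
        geoio.write_points_csv(out / "aeds_added_top.csv", table_b)
        combined = result.access.merge(predicted, on="cell_id").merge(
            counts, on="cell_id"
        )
        combined = combined.merge(
            ranked[["cell_id", "priority_rank"]], on="cell_id", how="left"
        )
        geoms = [grid.cell_polygon(c) for c in combined["cell_id"]]
        props = combined.drop(columns=[]).to_dict("records")
        for p in props:  # JSON-safe values
            for k, v in list(p.items()):
                if isinstance(v, (np.integer,)):
                    p[k] = int(v)
                elif isinstance(v, (np.floating,)):
                    p[k] = None if np.isnan(v) else float(v)
        geoio.write_geojson(out / "cells_combined.geojson", geoms, props)
        manifest["stages"]["rank"] = {
            "n_ranked": int(len(ranked)),
            "n_new_aeds_outside_grid": n_out,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("rank", "stage-failure", str(exc)) from exc

    manifest["runtime_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
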