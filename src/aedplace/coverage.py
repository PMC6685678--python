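"""Maximal covering location problem (MCLP) for new AED sites.

Choose ``N`` candidate buildings so that the number of historical OHCA events
within the coverage radius of at least one chosen site is maximal:

    max  sum_j x_j
    s.t. sum_i y_i = N
         x_j <= sum_i a_ji y_i        for every OHCA j
         x, y binary

with ``a_ji = 1`` iff OHCA ``j`` lies within the radius of candidate ``i``
(closed boundary: a distance exactly equal to the radius counts as covered).
Events already covered by existing AEDs are removed beforehand so the budget
only buys new coverage.

Three solvers are provided: an exact integer program (HiGHS via
``scipy.optimize.milp``), the classic greedy heuristic with its
``1 - 1/e`` guarantee, and exhaustive enumeration for small instances
(the test oracle).  Ties between equal-objective optima are broken
deterministically in favour of lower site ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix, eye, hstack

EARTH_RADIUS_M = 6_371_000.0


def haversine_matrix(points_a, points_b) -> np.ndarray:
    """Great-circle distance matrix in metres.

    Inputs are ``(n, 2)`` arrays of ``(lat, lon)`` in degrees.  Uses the
    haversine formula on a sphere of radius 6 371 000 m.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    for name, arr in (("points_a", a), ("points_b", b)):
        if arr.shape[1] != 2:
            raise ValueError(f"{name} must be an (n, 2) array of (lat, lon)")
        if np.any(np.abs(arr[:, 0]) > 90):
            raise ValueError(f"{name} has latitude outside [-90, 90]")
        if np.any(np.abs(arr[:, 1]) > 360):
            raise ValueError(f"{name} has longitude outside [-360, 360]")
    lat1 = np.radians(a[:, 0])[:, None]
    lat2 = np.radians(b[:, 0])[None, :]
    dlat = lat2 - lat1
    dlon = np.radians(b[:, 1])[None, :] - np.radians(a[:, 1])[:, None]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class CoverageProblem:
    """One MCLP instance: binary coverage matrix, ids and budget."""

    a: np.ndarray = field(repr=False)  # (J, I) boolean
    ohca_ids: np.ndarray = field(repr=False)
    site_ids: np.ndarray = field(repr=False)
    radius: float = 100.0
    N: int = 100

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=bool)
        self.ohca_ids = np.asarray(self.ohca_ids)
        self.site_ids = np.asarray(self.site_ids)
        J, I = self.a.shape
        if len(self.ohca_ids) != J or len(self.site_ids) != I:
            raise ValueError("id lengths must match the coverage matrix shape")
        if self.N < 0:
            raise ValueError("budget N must be nonnegative")
        if self.N > I:
            raise ValueError(f"budget N={self.N} exceeds {I} candidate sites")

    @property
    def n_ohca(self) -> int:
        return self.a.shape[0]

    @property
    def n_sites(self) -> int:
        return self.a.shape[1]


@dataclass
class CoverageSolution:
    """Selected sites, covered events, and optimality status."""

    selected: list
    covered: list
    objective: int
    optimal: bool

    def __post_init__(self) -> None:
        self.selected = sorted(self.selected)
        self.covered = sorted(self.covered)
        if self.objective != len(self.covered):
            raise ValueError("objective must equal the number of covered events")


def build_coverage_matrix(
    ohcas: pd.DataFrame, candidates: pd.DataFrame, radius: float
) -> np.ndarray:
    """Boolean ``a_ji``: OHCA ``j`` within ``radius`` metres of site ``i``.

    The boundary is closed (distance == radius counts).  Computed in row
    chunks so the full float distance matrix never materialises.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    P = ohcas[["lat", "lon"]].to_numpy(dtype=float)
    Q = candidates[["lat", "lon"]].to_numpy(dtype=float)
    J = len(P)
    out = np.empty((J, len(Q)), dtype=bool)
    chunk = max(1, int(4e6 // max(len(Q), 1)))
    for lo in range(0, J, chunk):
        hi = min(lo + chunk, J)
        out[lo:hi] = haversine_matrix(P[lo:hi], Q) <= radius
    return out


def remove_covered(
    ohcas: pd.DataFrame, existing_aeds: pd.DataFrame, radius: float
) -> tuple[pd.DataFrame, int]:
    """Drop OHCAs already within ``radius`` of an existing AED.

    Returns ``(uncovered subset, n_removed)``.  With no existing AEDs all
    OHCAs are retained.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(existing_aeds) == 0:
        return ohcas.copy(), 0
    cov = build_coverage_matrix(ohcas, existing_aeds, radius)
    already = cov.any(axis=1)
    return ohcas.loc[~already].copy(), int(already.sum())


def dedupe_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Collapse candidate sites at identical coordinates (keep lowest id)."""
    return candidates.drop_duplicates(subset=["lat", "lon"], keep="first")


def solve_mclp(problem: CoverageProblem) -> CoverageSolution:
    """Exact MCLP solution by integer programming (HiGHS).

    The coverage indicators ``x`` are relaxed to [0, 1] (they are integral at
    any optimum of the maximisation); site variables ``y`` stay binary.  A
    tiny monotone bonus on low site ids — strictly smaller than 1 in total,
    so it can never trade against the integer coverage objective — makes the
    reported optimum deterministic across solver versions.
    """
    J, I = problem.a.shape
    N = problem.N
    if N == 0 or J == 0:
        selected = sorted(problem.site_ids[:N].tolist())
        return CoverageSolution(selected=selected, covered=[], objective=0, optimal=True)
    A = csr_matrix(problem.a.astype(float))
    # variables: [x_1..x_J, y_1..y_I]
    tie = 0.4 * (I - np.arange(I)) / (I * (I + 1))
    c = -np.concatenate([np.ones(J), tie])
    cons_cover = LinearConstraint(
        hstack([eye(J, format="csr"), -A], format="csr"), -np.inf, 0.0
    )
    cons_budget = LinearConstraint(
        np.concatenate([np.zeros(J), np.ones(I)])[None, :], N, N
    )
    integrality = np.concatenate([np.zeros(J), np.ones(I)])
    res = milp(
        c=c,
        constraints=[cons_cover, cons_budget],
        bounds=Bounds(0.0, 1.0),
        integrality=integrality,
    )
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    x = res.x[:J] > 0.5
    y = res.x[J:] > 0.5
    selected = problem.site_ids[y].tolist()
    covered = problem.ohca_ids[x].tolist()
    return CoverageSolution(
        selected=selected, covered=covered, objective=int(round(x.sum())), optimal=True
    )


def greedy_mclp(problem: CoverageProblem) -> CoverageSolution:
    """Greedy MCLP: repeatedly add the site covering most uncovered events.

    Ties go to the lowest site id.  By submodularity the greedy objective is
    at least ``(1 - 1/e)`` times the optimum.  If the budget exceeds the
    number of useful sites, remaining picks fall to the lowest-id unselected
    sites so that exactly ``N`` sites are always returned.
    """
    J, I = problem.a.shape
    a = problem.a
    uncovered = np.ones(J, dtype=bool)
    chosen: list[int] = []
    for _ in range(problem.N):
        gains = a[uncovered].sum(axis=0) if uncovered.any() else np.zeros(I)
        gains = np.asarray(gains, dtype=float)
        gains[chosen] = -1.0
        best = int(np.argmax(gains))  # argmax returns the first (lowest) index on ties
        chosen.append(best)
        uncovered &= ~a[:, best]
    covered = ~uncovered if problem.N else np.zeros(J, dtype=bool)
    return CoverageSolution(
        selected=problem.site_ids[sorted(chosen)].tolist(),
        covered=problem.ohca_ids[covered].tolist(),
        objective=int(covered.sum()),
        optimal=False,
    )


def brute_force_mclp(problem: CoverageProblem, max_combinations: float = 1e6) -> CoverageSolution:
    """Exhaustive MCLP optimum — the oracle for small instances.

    Enumerates all C(I, N) site subsets (refusing above
    ``max_combinations``); the first subset attaining the best objective in
    lexicographic order is returned, matching the exact solver's tie-break.
    """
    J, I = problem.a.shape
    if math.comb(I, problem.N) > max_combinations:
        raise ValueError(
            f"C({I}, {problem.N}) exceeds the enumeration bound {max_combinations:g}"
        )
    best_obj = -1
    best_sel: tuple[int, ...] = ()
    best_cov = np.zeros(J, dtype=bool)
    for sel in combinations(range(I), problem.N):
        cov = problem.a[:, sel].any(axis=1) if sel else np.zeros(J, dtype=bool)
        obj = int(cov.sum())
        if obj > best_obj:
            best_obj, best_sel, best_cov = obj, sel, cov
    return CoverageSolution(
        selected=problem.site_ids[list(best_sel)].tolist(),
        covered=problem.ohca_ids[best_cov].tolist(),
        objective=best_obj,
        optimal=True,
    )
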