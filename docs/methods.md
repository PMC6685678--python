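# Methods

## The occurrence model

Counts are modelled per grid cell, not per municipality: a 0.01° lon/lat
lattice (≈1.1 km cells at mid-latitudes) is laid over the region, each cell
is attributed to the municipality containing its centroid, and municipality
covariates are divided equally among that municipality's cells. The equal
division conserves municipality totals exactly but assumes covariates are
uniform within a municipality — a deliberate simplification that matches
the resolution of typical administrative data.

The count model is a type-1 zero-inflated Poisson: a cell is a structural
zero with global probability `p = logistic(θ)`, otherwise Poisson with
`log λ_i = β0 + x_i·β + u_i + v_i`. The random-effect pair (u, v) is the
BYM decomposition: `u` is an intrinsic CAR field — each `u_i` conditionally
normal around the mean of its lattice neighbours with precision `τ_u n_i` —
and `v` is iid `Normal(0, σ_v)`. Rook contiguity is the default neighbour
definition (queen available by flag). The ICAR prior is improper; `u` is
identified by keeping it centred and absorbing its mean into the intercept
at every sampler iteration, the standard lattice-model identification.

### Priors

* `θ ~ Normal(1e-6, variance 2)`. The second argument is read as a
  **variance**: of the variance/sd/precision readings, variance 2 implies
  prior 2.5th/97.5th percentiles of p ≈ (0.06, 0.94), closest to the
  intended (0.05, 0.95), and a prior mean of exactly 0.5 by symmetry.
* `β0, β_m ~ Normal(0, sd 10)` — effectively flat at the data's scale.
* `τ_u, τ_v = 1/σ_v² ~ Gamma(1, 0.1)`. This default was chosen by
  simulation-based calibration: the older vague lattice default
  Gamma(1, 5e-4) is nearly flat up to precisions of thousands and puts
  ~0.5% of its mass below τ = 10, which over-smooths the spatial field and
  leaves the covariate credible intervals under-calibrated (≈79% coverage
  at nominal 90% in our replicate experiment) via spatial confounding with
  the municipality-blocked covariates. Gamma(1, 0.1) keeps honest mass on
  random-effect standard deviations in the (0.1, 2) range typical of
  log-linear count models and restores ≈87–90% coverage. Both choices are
  exposed in `ZipCarPriorSpec`.

### Inference

The posterior is sampled with an adaptive Metropolis-within-Gibbs scheme
written for this lattice structure:

* `(β0, β)` — joint random-walk block whose proposal covariance is learned
  from the chain history (Haario-style adaptive Metropolis, with a small
  safeguard kernel), four proposals per sweep; covariates are standardised
  internally and coefficients reported on both scales;
* `u` — vectorised single-site random walks, updated one graph-colour class
  at a time (same-colour cells are conditionally independent under the
  ICAR Markov property; a rook lattice needs two colours);
* `v` — fully vectorised independent random walks;
* `τ_u, τ_v` — conjugate Gamma draws;
* one joint scale move per sweep on each (field, precision) pair,
  `(u, τ_u) → (cu, τ_u/c²)`, which leaves the ICAR density invariant and
  breaks the usual funnel between a field and its precision;
* `θ` — scalar random walk.

Proposal scales adapt toward standard acceptance targets during warmup only;
the kernel is fixed afterwards. Convergence is summarised by split-R̂ on
β0, each β_m, θ, log τ_u and log σ_v; a fit with any R̂ ≥ 1.05 is flagged
`converged = False` and the pipeline records the warning in its manifest.
All randomness flows from one integer seed; identical seeds give
bit-identical draws.

The sampler was validated two ways before use: against a statsmodels
Poisson GLM on Poisson-only data (posterior z-scores and coverage match the
MLE's sampling distribution), and by simulation-based calibration on the
full model — 50 replicates at 400 cells with known generative parameters,
where the pooled coverage of 90% credible intervals is ≈87% and every
component's posterior mean falls within 3 posterior sds of the truth in
≥98% of replicates. The test suite re-runs this experiment.

### Predicted demand

"Predicted count" for a cell is the posterior mean of the **ZIP mean**
`(1−p)λ_i` by default (the λ-only mean is available by flag). Note that the
ZIP mean legitimately exceeds the observed count in cells the model reads
as structural zeros with high λ; summed over cells it can therefore sit
above the observed total when the covariates imply heavy-tailed rates.

### Residual diagnostics

Global Moran's I is computed on (observed − posterior mean) residuals with
binary contiguity weights, `I = (n/S0)·(z'Wz)/(z'z)`, and a permutation
p-value `(1 + #extreme)/(n_perm + 1)`; the default alternative is
"greater" (positive clustering), the conventional one-sided test.

## Access scores (2SFCA)

Step 1: `R_j = S_j / Σ_k D_k G(d_kj, d0)` with supply `S_j = 1` per AED and
demand points within `d0` of AED j. Step 2: `A_i = Σ R_j` over AEDs inside
cell i.

* **Demand points are cell centroids** carrying the posterior-mean
  predicted count. This matters: with the default `d0 = 100 m` and ≈1.1 km
  cells, an AED's catchment contains a centroid only if the AED happens to
  sit near the middle of its cell. Most AEDs therefore have an **empty
  catchment**; their ratio is set to `R_j = 0` and flagged
  (`zero_demand = True`) rather than left undefined or infinite — an
  unbounded ratio would dominate every ranking. The flagged list is
  reported so users can audit the choice. Raising `d0` to 250 m (supported)
  or ranking at larger radii softens the mismatch.
* The decay kernel is the truncated Gaussian
  `G = (e^{-(d/d0)²/2} − e^{-1/2}) / (1 − e^{-1/2})` for `d ≤ d0`, zero
  beyond: 1 at distance zero, continuously and strictly decreasing to 0 at
  `d0`. A piecewise-constant stepwise kernel is available; its default —
  a single step of weight 1 on [0, d0] — is plain binary coverage, and
  arbitrary nonincreasing break tables are accepted.
* Distances are great-circle (haversine, sphere radius 6 371 000 m).
* All AEDs count as supply by default; a flag restricts supply to 24/7
  public devices (availability is recorded per AED).

Conservation holds by construction: the sum of access scores over cells
equals the sum of ratios over in-grid AEDs. Note that increasing `d0` does
**not** monotonically increase `R_j` — a larger catchment adds demand to
the denominator — which is documented behaviour, not a bug.

## Coverage optimisation (MCLP)

`max Σ_j x_j` subject to `Σ_i y_i = N` and `x_j ≤ Σ_i a_ji y_i`, with
`a_ji = 1` iff OHCA j lies within the radius of candidate i. Events already
within the radius of an existing AED are removed first.

* The coverage boundary is **closed** (distance exactly equal to the radius
  counts), chosen alongside the access kernel's convention (G reaches 0
  exactly at d0) and documented here because the two conventions differ at
  the boundary by design: coverage is binary, the kernel is continuous.
* The exact solver is an integer program (HiGHS via `scipy.optimize.milp`);
  the coverage indicators are relaxed to [0, 1], which is lossless at any
  optimum. A monotone bonus on low site ids, strictly below 1 in total,
  makes the selected set deterministic across solver versions without ever
  trading against the integer objective.
* The greedy heuristic (largest marginal coverage, ties to the lowest site
  id) carries the classic `1 − 1/e` submodularity guarantee and serves as a
  fast fallback; exhaustive enumeration (`C(I, N) ≤ 10⁶`) is the test
  oracle.
* Candidate sites at identical coordinates are collapsed before solving to
  avoid degenerate alternate optima.

## Priority ranking

Cells with predicted count above the threshold (default 1) are sorted by
ascending access, ties by descending predicted count, final ties by cell id
— a deterministic total order. Placement solutions are evaluated by
point-in-cell counts of the selected sites: table A lists the top-k
priority areas with their new-AED counts, table B the top-k areas by AEDs
received (ties broken by better priority rank). The urban/rural label is an
input attribute on municipalities, propagated to cells; no classification
rule is applied.

## The synthetic generator

The generator emulates the structure of a Ticino-like case study, not its
geography:

* **Region**: a lattice partitioned into contiguous municipalities by
  seeded region growing (115 municipalities by default, the emulated
  administrative scale, on a 24×24 lattice — a desk-scale stand-in for the
  case study's ~3205 cells).
* **Covariates**: proportions from Beta distributions, land-use hectares
  from a Dirichlet split of a log-normal built-area total, population
  density and financial strength log-normal; the top 30% of municipalities
  by population density are labelled urban. These are range-respecting
  stand-ins, not calibrated marginals.
* **Counts**: drawn from exactly the fitted model — ICAR field sampled by
  eigendecomposition of the constrained precision (the null eigenvector
  dropped, so every draw sums to zero and the draw covariance equals the
  scaled pseudo-inverse of τ(D − W)), iid v, global structural-zero
  probability. Default truth: β0 = 0.56 (≈1.75 expected events per at-risk
  cell, reproducing the case-study event density of ~0.9 per cell once
  p = 0.5 is applied), standardised effect sizes |β| ≤ 0.25 with the signs
  the occurrence literature reports, τ_u = 4, σ_v = 0.25.
* **Points**: event coordinates uniform within their cell (the model is
  cell-level; within-cell position only matters at coverage radii, and
  uniform is the least-informative choice); 719 AEDs with a 60/40
  public/time-limited availability split and 5000 candidate buildings
  (down-sampled from the case study's ~118 000) uniform over the modelled
  region.

What passing tests on this generator do **not** show: behaviour under real
road-network distances, non-uniform within-cell event placement, covariate
maps with realistic spatial gradients, or municipality shapes that are not
unions of grid cells.

## Numerical and interface choices

* Cell intervals are half-open `[x, x + size)` in both axes; every point
  maps to exactly one cell and edge events have a deterministic home. The
  grid origin is the region bounding box's lower-left corner.
* Cells whose centroid falls outside every municipality carry no covariates
  and are excluded from the model and rankings.
* CSV outputs are written with a fixed float format (`%.10g`) so reruns
  with identical seeds are byte-identical; the pipeline manifest records
  the config hash, seeds and per-stage row counts.
* Problem sizes in the test suite are chosen for a desk machine: the
  calibration experiment uses 50 replicates of 400 cells at 3000 warmup /
  3500 kept draws; the full-region analysis scripts default to 8000 / 12000
  on 576 cells.
* The package exposes its functionality as a library plus the numbered
  analysis scripts; there is no separate console command. The pipeline
  module (`PipelineConfig`, `run_pipeline`, `validate_inputs`) is the
  single-call reproducible entry point.

## Known limitations

* Straight-line distances only; road networks and travel times are out of
  scope.
* The zero-inflation probability is global. Cell-level zero-inflation
  would need a different identification strategy.
* The 100 m catchment against ~1.1 km demand cells makes raw access scores
  sparse (most are 0); rankings remain well-defined but coarse.
* MCLP instances with very many candidates are solved exactly; for
  instances beyond the integer programme's patience the greedy solver is
  the intended fallback (`solver: greedy` in the pipeline config).
* Municipality covariates are treated as exact; no measurement-error model.
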