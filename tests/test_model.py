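import numpy as np
import pytest
from scipy.stats import poisson, spearmanr

from aedplace.gridding import build_adjacency, build_grid, disaggregate_covariates
from aedplace.model import (
    ZipCarPriorSpec,
    build_linear_predictor,
    fit,
    icar_log_density,
    morans_i,
    prior_p_summary,
    split_rhat,
    zip_log_likelihood,
)
from aedplace.synthetic import (
    GenerativeParams,
    SyntheticRegionConfig,
    generate_covariates,
    generate_region,
    simulate_ohca_data,
    study_params,
)


class TestZipLogLikelihood:
    def test_zero_count_mixture_value(self):
        # log(0.5 + 0.5 e^{-1})
        assert zip_log_likelihood([0], [1.0], 0.5) == pytest.approx(-0.3798855, abs=1e-6)

    def test_reduces_to_poisson_at_p_zero(self, rng):
        y = rng.poisson(2.0, size=40)
        lam = rng.uniform(0.5, 5.0, size=40)
        ours = zip_log_likelihood(y, lam, 0.0)
        assert ours == pytest.approx(poisson.logpmf(y, lam).sum(), rel=1e-12)
        # spot value: p=0, y=2, lambda=2
        assert zip_log_likelihood([2], [2.0], 0.0) == pytest.approx(-1.3068528, abs=1e-6)

    def test_degenerate_mixture_impossible_outcome(self):
        assert zip_log_likelihood([1], [1.0], 1.0) == -np.inf

    @pytest.mark.parametrize(
        "y, lam, p", [([-1], [1.0], 0.5), ([0.5], [1.0], 0.5), ([0], [0.0], 0.5), ([0], [1.0], 1.5)]
    )
    def test_invalid_inputs_rejected(self, y, lam, p):
        with pytest.raises(ValueError):
            zip_log_likelihood(y, lam, p)


class TestPriorPSummary:
    def test_point_mass_prior(self):
        prior = ZipCarPriorSpec(theta_mean=0.0, theta_variance=1e-12)
        s = prior_p_summary(prior, n_draws=1000, seed=0)
        assert s["mean"] == pytest.approx(0.5, abs=1e-6)

    def test_percentiles_symmetric_about_half(self):
        prior = ZipCarPriorSpec(theta_mean=0.0, theta_variance=2.0)
        s = prior_p_summary(prior, n_draws=200_000, seed=1)
        assert s["q2.5"] + s["q97.5"] == pytest.approx(1.0, abs=0.01)


class TestLinearPredictor:
    def test_zero_predictor_gives_unit_rate(self):
        lam = build_linear_predictor(np.zeros((3, 2)), 0.0, [0, 0], np.zeros(3), np.zeros(3))
        assert np.allclose(lam, 1.0)

    def test_intercept_only(self):
        lam = build_linear_predictor(np.zeros((2, 1)), np.log(3), [0], np.zeros(2), np.zeros(2))
        assert np.allclose(lam, 3.0)

    def test_intercept_shift_scales_rates(self, rng):
        X = rng.normal(size=(5, 3))
        u, v = rng.normal(size=5), rng.normal(size=5)
        a = build_linear_predictor(X, 0.2, [1, -1, 0.5], u, v)
        b = build_linear_predictor(X, 1.2, [1, -1, 0.5], u, v)
        assert np.allclose(b, np.e * a)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            build_linear_predictor(np.zeros((3, 2)), 0.0, [0.0], np.zeros(3), np.zeros(3))


class TestIcarLogDensity:
    def test_zero_field(self, rook_adjacency_5x5):
        assert icar_log_density(np.zeros(25), rook_adjacency_5x5, 3.0) == 0.0

    def test_two_cell_pair_difference(self):
        adj = {0: [1], 1: [0]}
        a, tau = 0.7, 1.3
        expected = -(tau / 2) * (2 * a) ** 2
        assert icar_log_density([a, -a], adj, tau) == pytest.approx(expected)

    def test_linear_in_precision(self, rook_adjacency_5x5, rng):
        u = rng.normal(size=25)
        u -= u.mean()
        d1 = icar_log_density(u, rook_adjacency_5x5, 1.0)
        assert icar_log_density(u, rook_adjacency_5x5, 2.0) == pytest.approx(2 * d1)

    def test_invariant_to_constant_shift(self, rook_adjacency_5x5, rng):
        u = rng.normal(size=25)
        d1 = icar_log_density(u, rook_adjacency_5x5, 1.5)
        d2 = icar_log_density(u + 3.7, rook_adjacency_5x5, 1.5)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        grid = build_grid((0.0, 0.0, 0.02, 0.02), 0.01)
        adj = build_adjacency(grid, "rook")
        I, _ = morans_i([1.0, -1.0, -1.0, 1.0], adj, n_permutations=9, seed=0)
        assert I == pytest.approx(-1.0, abs=1e-12)

    def test_constant_residuals_rejected(self, rook_adjacency_5x5):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(25), rook_adjacency_5x5, n_permutations=9, seed=0)

    def test_smooth_field_detected(self, grid_5x5, rook_adjacency_5x5):
        # strongly autocorrelated residuals: a lon gradient
        z = grid_5x5.cells["centroid_lon"].to_numpy()
        I, p = morans_i(z, rook_adjacency_5x5, n_permutations=199, seed=1)
        assert I > 0.5 and p < 0.05


class TestSplitRhat:
    def test_stationary_chain_near_one(self, rng):
        assert split_rhat(rng.normal(size=4000)) < 1.02

    def test_trending_chain_flagged(self):
        assert split_rhat(np.linspace(0, 1, 4000)) > 1.5


def _simulated_cells(n_side, n_muni, params, seed):
    config = SyntheticRegionConfig(
        lattice_rows=n_side, lattice_cols=n_side, n_municipalities=n_muni, seed=seed
    )
    munis, grid = generate_region(config)
    munis = generate_covariates(munis, seed=seed + 1)
    cells = disaggregate_covariates(munis, grid.cells)
    ds = simulate_ohca_data(grid, cells, params, seed=seed + 2)
    return grid, ds


@pytest.fixture(scope="module")
def fitted():
    params = study_params()
    grid, ds = _simulated_cells(10, 12, params, seed=21)
    adj = build_adjacency(grid, "rook")
    post = fit(ds.cells, adj, draws=2000, warmup=2000, seed=5)
    return params, ds, post


class TestFit:
    def test_posterior_shapes_and_ranges(self, fitted):
        _, ds, post = fitted
        assert post.draws["p"].shape == (2000,)
        assert ((post.draws["p"] > 0) & (post.draws["p"] < 1)).all()
        assert (post.draws["tau_u"] > 0).all()
        assert (post.pred_mean >= 0).all()
        assert abs(post.u_mean.sum()) < 1e-6
        assert len(post.coef_table()) == 10  # intercept + 9 covariates

    def test_residuals_roughly_centred(self, fitted):
        _, ds, post = fitted
        assert abs(post.residual.mean()) < 0.1 * post.y.mean()

    def test_likelihood_consistency_of_predictions(self, fitted):
        # ZIP mean is (1-p) lambda, so the two prediction kinds must be
        # ordered and close to proportional
        _, _, post = fitted
        assert (post.predicted("zip_mean") <= post.predicted("lambda") + 1e-9).all()

    def test_identical_seed_identical_draws(self):
        params = study_params()
        grid, ds = _simulated_cells(6, 4, params, seed=31)
        adj = build_adjacency(grid, "rook")
        p1 = fit(ds.cells, adj, draws=150, warmup=150, seed=9)
        p2 = fit(ds.cells, adj, draws=150, warmup=150, seed=9)
        assert np.array_equal(p1.draws["beta"], p2.draws["beta"])
        assert np.array_equal(p1.pred_mean, p2.pred_mean)

    def test_predictions_track_truth_when_signal_dominates(self):
        # strong covariate signal, weak noise: predictions must rank cells
        # like the observations (the observed-vs-fitted check)
        params = GenerativeParams(
            beta0=1.0,
            beta=2 * study_params().beta,
            tau_u=10.0,
            sigma_v=0.1,
            p_zero=0.2,
        )
        grid, ds = _simulated_cells(20, 40, params, seed=41)
        adj = build_adjacency(grid, "rook")
        post = fit(ds.cells, adj, draws=1200, warmup=1200, seed=6)
        rho = spearmanr(post.pred_mean, post.y).statistic
        assert rho > 0.5

    def test_too_few_cells_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="2 cells"):
            fit(pd.DataFrame({"cell_id": [0], "y": [1]}), {0: []}, draws=10, warmup=10)

    def test_disconnected_adjacency_rejected(self):
        import pandas as pd

        cells = pd.DataFrame({"cell_id": [0, 1, 2, 3], "y": [0, 1, 0, 2], "x": [0.0, 1, 2, 3]})
        adj = {0: [1], 1: [0], 2: [3], 3: [2]}
        with pytest.raises(ValueError, match="connected"):
            fit(cells, adj, draws=10, warmup=10)
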