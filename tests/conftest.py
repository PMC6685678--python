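import numpy as np
import pytest

from aedplace.gridding import build_adjacency, build_grid
from aedplace.pipeline import write_synthetic_bundle
from aedplace.synthetic import (
    GenerativeParams,
    SyntheticRegionConfig,
    generate_study_bundle,
    study_params,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study: 12x12 lattice, 18 municipalities."""
    config = SyntheticRegionConfig(
        lattice_rows=12, lattice_cols=12, n_municipalities=18, seed=7
    )
    params = GenerativeParams(
        beta0=0.56, beta=study_params().beta, n_aeds=80, n_buildings=400
    )
    return generate_study_bundle(config, params)


@pytest.fixture(scope="session")
def small_bundle_paths(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return write_synthetic_bundle(small_bundle, out)


@pytest.fixture()
def grid_5x5():
    return build_grid((0.0, 0.0, 0.05, 0.05), 0.01)


@pytest.fixture()
def rook_adjacency_5x5(grid_5x5):
    return build_adjacency(grid_5x5, "rook")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
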