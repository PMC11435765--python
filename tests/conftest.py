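import numpy as np
import pytest

import pmburden as pb


@pytest.fixture(scope="session")
def gemm_params():
    return pb.load_gemm_parameters()


@pytest.fixture(scope="session")
def small_study():
    """20x20, 3 regions, 2 anchor years — the bundled smoke fixture."""
    cfg = pb.SyntheticStudyConfig(
        grid_rows=20, grid_cols=20, n_regions=3, years=(2007, 2022),
        population_total=50_000, seed=11)
    return pb.generate_study(cfg)


@pytest.fixture(scope="session")
def medium_study():
    """100x100 default-condition study used for recovery checks."""
    return pb.generate_study(pb.SyntheticStudyConfig(seed=4))


@pytest.fixture
def rng():
    return np.random.default_rng(20240831)
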