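import numpy as np
import pytest

import feedsel as fs


@pytest.fixture(scope="session")
def trait_params():
    params, _ = fs.load_parameter_fixtures(consistency="ignore")
    return params


@pytest.fixture(scope="session")
def printed_corr():
    _, corr = fs.load_parameter_fixtures(consistency="ignore")
    return corr


@pytest.fixture(scope="session")
def full_corr():
    """Complete correlation structure (synthetic core block, seed 2021)."""
    return fs.generate_core_correlations(seed=2021)


@pytest.fixture(scope="session")
def index_matrices(trait_params, full_corr):
    return fs.build_gebv_index_matrices(trait_params, full_corr.rg)


@pytest.fixture(scope="session")
def sigma_g(trait_params):
    return np.array([p.sigma_g for p in trait_params])
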