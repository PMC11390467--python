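import numpy as np
import pytest

import predseek as ps


@pytest.fixture(scope="session")
def predation_params() -> ps.ModelParams:
    return ps.predation_preset()


@pytest.fixture(scope="session")
def single_factor_params() -> ps.ModelParams:
    return ps.single_factor_preset()


@pytest.fixture(scope="session")
def noiseless_ensemble(predation_params):
    """8 noiseless heterogeneous regions from the predation preset."""
    series = ps.generate_ensemble(
        predation_params,
        n_regions=8,
        n_days=61,
        noise=ps.NoiseSpec(sigma_frac=0.0, seed=2024),
    )
    return [ps.cumulate(s) for s in series]


@pytest.fixture(scope="session")
def noisy_ensemble(predation_params):
    """8 regions with 0.5%-of-K daily-increment noise."""
    series = ps.generate_ensemble(
        predation_params,
        n_regions=8,
        n_days=61,
        noise=ps.NoiseSpec(sigma_frac=0.005, seed=2024),
    )
    return [ps.cumulate(s) for s in series]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
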