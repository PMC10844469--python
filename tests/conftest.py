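import numpy as np
import pytest

from microstim import (
    CultureConfig,
    DispenseConditions,
    ResponseModelParams,
    generate_culture,
    simulate_response,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cluster_cond():
    return DispenseConditions(c0_nM=318.0, mode="cluster", duration_s=300.0)


@pytest.fixture
def single_cell_cond():
    return DispenseConditions(c0_nM=5500.0, mode="single_cell", duration_s=300.0)


@pytest.fixture
def response_params():
    return ResponseModelParams()


@pytest.fixture
def sparse_culture():
    return generate_culture(CultureConfig(density=400.0, seed=11))


@pytest.fixture
def stimulated_culture(sparse_culture):
    """A sparse culture under a uniform 100 nM bath for 5 minutes."""
    return simulate_response(sparse_culture, 100.0, 5.0, seed=21, density=400.0)
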