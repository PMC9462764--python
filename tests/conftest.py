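import numpy as np
import pytest

from episkin import kinetics
from episkin.coupling import CouplingConfig, ModelParams
from episkin.mechanics import Domain


@pytest.fixture(scope="session")
def single_cell_rates():
    return kinetics.SINGLE_CELL_RATES


@pytest.fixture(scope="session")
def multiscale_rates():
    return kinetics.MULTISCALE_RATES


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model():
    """A 4x4 model with a low provisional ceiling for quick coupled runs."""
    return ModelParams(
        domain=Domain(4.0, 4.0),
        coupling=CouplingConfig(seed=7, fill_ceiling=8.0,
                                burn_in_days=0.0, sample_days=1.0),
    )


def random_chem_states(rng, n, params, rates):
    """Random states satisfying all three conservation laws exactly."""
    eps = params.eps
    e = rng.uniform(0, 1, n)
    c_i_max = np.minimum(1 - e, params.i_T / params.s_0 / eps if eps > 0 else 1 - e)
    c_i = rng.uniform(0, 1, n) * c_i_max
    c_s = 1 - e - c_i
    i = params.i_T / params.s_0 - eps * c_i
    s = rng.uniform(0, 1, n) * (1 - eps * c_s)
    p = 1 - s - eps * c_s
    return np.column_stack([e, s, i, c_s, c_i, p])
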