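import numpy as np
import pytest

from qdwiqc import (NoiseModel, default_layout, qiba_phantom_params,
                    simulate_repeated_exams, small_layout)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def mc_layout():
    """Compact layout for Monte-Carlo tests."""
    return small_layout()


@pytest.fixture(scope="session")
def qiba_params():
    return qiba_phantom_params()


@pytest.fixture(scope="session")
def noiseless_exams(layout, qiba_params):
    return simulate_repeated_exams(layout, qiba_params, NoiseModel(),
                                   n_repeats=4, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
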