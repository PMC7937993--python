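import numpy as np
import pytest

from optcc import (
    CANONICAL_GRID,
    build_shell,
    candidate_grid,
    default_fundamentals,
    enumerate_optimal_reflectances,
    equal_energy_white,
)
from optcc.optimal import build_shell_from_spectrum


@pytest.fixture(scope="session")
def fundamentals():
    return default_fundamentals()


@pytest.fixture(scope="session")
def optimal_set():
    return enumerate_optimal_reflectances(CANONICAL_GRID)


@pytest.fixture(scope="session")
def shell_6500():
    return build_shell(6500.0)


@pytest.fixture(scope="session")
def eew_shell(optimal_set, fundamentals):
    return build_shell_from_spectrum(
        equal_energy_white(), optimal_set, fundamentals, label="EEW"
    )


@pytest.fixture(scope="session")
def default_grid():
    return candidate_grid()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
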