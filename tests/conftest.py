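import numpy as np
import pytest

from lightodr import (
    SyntheticScenario,
    generate_lattice_zones,
    lattice_queen_weights,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def lattice_3x3():
    return generate_lattice_zones(3, 3)


@pytest.fixture
def queen_5x5_row():
    return lattice_queen_weights(5, 5).row_standardized()


@pytest.fixture
def noiseless_scenario():
    return SyntheticScenario(seed=11, noise_sd=0.0)
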