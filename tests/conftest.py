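import numpy as np
import pytest

from nucdens.fixtures import chain_model, chain_zero_modes, water_model
from nucdens.harmonic import normal_mode_analysis


@pytest.fixture(scope="session")
def water():
    """(system, hessian, modes) for the H2O valence-force-field fixture."""
    system, hess = water_model()
    return system, hess, normal_mode_analysis(system, hess)


@pytest.fixture(scope="session")
def hdo():
    """(system, hessian, modes) for mono-deuterated water (same Hessian)."""
    system, hess = water_model(isotopes=("O", "D", "H"))
    return system, hess, normal_mode_analysis(system, hess)


@pytest.fixture(scope="session")
def chain2():
    """(system, hessian, modes) for two unit masses joined by a unit spring."""
    system, hess = chain_model(2)
    modes = normal_mode_analysis(system, hess, n_zero=chain_zero_modes(2))
    return system, hess, modes


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
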