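import numpy as np
import pytest

from busulfanpk import model_core as mc
from busulfanpk.virtual_trial import TYPICAL_PATIENT


@pytest.fixture(scope="session")
def pop():
    """Reference population parameters (the generative truth)."""
    return mc.PopulationParameters()


@pytest.fixture(scope="session")
def typical():
    """The typical virtual patient (1.4 y, 9.9 kg, GST 10.12)."""
    return TYPICAL_PATIENT


@pytest.fixture(scope="session")
def typical_individual(pop, typical):
    return mc.individual_parameters(pop, typical)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study_regimen_16():
    """16-dose q6h 2-h infusion regimen for the typical patient at 1 mg/kg."""
    return [mc.DosingEvent(6.0 * k, 9.9, 2.0) for k in range(16)]
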