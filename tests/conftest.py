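import warnings

import numpy as np
import pytest

from renalkin import FitOptions, fit_kidney, preprocess
from renalkin.synthetic_data import SyntheticSpec, make_kidney

# parameter-at-bound warnings are expected in edge-case fits (e.g. T_d = 0)
warnings.filterwarnings("ignore", message=".*parameters at bounds.*")


@pytest.fixture(scope="session")
def noiseless_kidney():
    """One synthetic kidney at default (typical hypertensive) parameters, no noise."""
    return make_kidney(SyntheticSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_kidney():
    return make_kidney(SyntheticSpec(noise_sd=3.0, seed=7))


@pytest.fixture(scope="session")
def prepped_noiseless(noiseless_kidney):
    kidney, truth = noiseless_kidney
    return preprocess(kidney, dt=0.5, t_max=120.0), truth


@pytest.fixture(scope="session")
def fit_noiseless(prepped_noiseless):
    prepped, truth = prepped_noiseless
    return fit_kidney(prepped, FitOptions(seed=1)), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
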