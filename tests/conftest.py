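import numpy as np
import pytest

from gaitkin import GaitModelParams, simulate_trial


@pytest.fixture(scope="session")
def noiseless_params() -> GaitModelParams:
    return GaitModelParams(noise_sigma_px=0.0, dropout_prob=0.0, duration_s=10.0)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_params):
    """One clean sagittal trial shared across read-only tests."""
    return simulate_trial(noiseless_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
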