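import numpy as np
import pytest

import plrkit as pk
from plrkit import calibration as cal


@pytest.fixture(scope="session")
def linear_truth():
    """Noiseless additive engine with identity (linear) channel response."""
    return pk.EngineGroundTruth.default()


@pytest.fixture(scope="session")
def curved_truth():
    """Noiseless engine with a planted beta-CDF nonlinearity (alpha=2, beta=3)."""
    return pk.EngineGroundTruth.default(alpha=2.0, beta=3.0)


@pytest.fixture(scope="session")
def linear_ctx(linear_truth):
    table = cal.acquire_calibration(linear_truth, seed=0)
    return cal.build_context(table)


@pytest.fixture(scope="session")
def curved_ctx(curved_truth):
    table = cal.acquire_calibration(curved_truth, seed=0)
    return cal.build_context(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
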