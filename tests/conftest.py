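import numpy as np
import pytest

from reachdim import (
    AnthropometricProfile,
    SessionConfig,
    estimate_segment_parameters,
    generate_session,
)

# the four subjects whose model parameters are printed in the study table
SUBJECTS = {
    1: dict(H=180.0, W=84.0),
    2: dict(H=162.0, W=58.0),
    3: dict(H=177.0, W=75.0),
    4: dict(H=181.0, W=78.0),
}


@pytest.fixture(scope="session")
def profile():
    return AnthropometricProfile(height=180.0, weight=84.0)


@pytest.fixture(scope="session")
def model(profile):
    return estimate_segment_parameters(profile)


@pytest.fixture(scope="session")
def small_session(model):
    """Four frontal center-out conditions, two repetitions, default noise."""
    cfg = SessionConfig(
        planes=("frontal",), n_targets=4, directions=("out",), repetitions=2, seed=42
    )
    trials, gt = generate_session(model, cfg)
    return trials, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
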