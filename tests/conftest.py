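import pytest

from trackcea import default_inputs, expected_outcomes
from trackcea.tree import StrategyParams


@pytest.fixture(scope="session")
def inputs():
    """Published base-case model inputs."""
    return default_inputs()


@pytest.fixture(scope="session")
def tracking_params(inputs):
    return StrategyParams.from_inputs(inputs, "tracking")


@pytest.fixture(scope="session")
def no_tracking_params(inputs):
    return StrategyParams.from_inputs(inputs, "no_tracking")


@pytest.fixture(scope="session")
def base_arms(tracking_params, no_tracking_params):
    """Base-case expectations (tracking, no_tracking)."""
    return expected_outcomes(tracking_params), expected_outcomes(no_tracking_params)
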