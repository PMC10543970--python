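import numpy as np
import pytest

from fermsense import (
    CAMPAIGN_MEDIA,
    SimulatorParams,
    design_feed_policy,
    simulate_batch,
    simulate_fedbatch,
)


@pytest.fixture(scope="session")
def params():
    return SimulatorParams()


@pytest.fixture(scope="session")
def noiseless_params(params):
    return params.noiseless()


@pytest.fixture(scope="session")
def batch_run(noiseless_params):
    """Noiseless 24 h batch run on the lactose medium."""
    return simulate_batch(CAMPAIGN_MEDIA[1], noiseless_params, 24.0, seed=42)


@pytest.fixture(scope="session")
def noisy_batch_run(params):
    return simulate_batch(CAMPAIGN_MEDIA[1], params, 24.0, seed=42)


@pytest.fixture(scope="session")
def fedbatch_run(noiseless_params):
    """Noiseless fed-batch run at the 0.19 h^-1 setpoint."""
    media = CAMPAIGN_MEDIA[7]
    policy = design_feed_policy(media, noiseless_params, 0.19)
    series, offline = simulate_fedbatch(media, policy, noiseless_params, 24.0, seed=43)
    return series, offline, policy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
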