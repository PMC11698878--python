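import numpy as np
import pytest

from staircurve import CohortConfig, ObserverModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def observer():
    """Default learner with the trained-arm mean parameters."""
    return ObserverModel(
        subject_id="S001", alpha=8.29, beta=8.12, gamma=1.89,
        slope=6.0, lapse=0.02, age=75.0, group="training",
    )


@pytest.fixture
def stationary_observer():
    """Non-learning observer: negligible learning amount, flat threshold."""
    return ObserverModel(
        subject_id="S000", alpha=1e-12, beta=1.0, gamma=5.0,
        slope=6.0, lapse=0.02, age=70.0, group="training",
    )


@pytest.fixture
def small_config():
    """A cohort small enough for fast end-to-end runs."""
    return CohortConfig(n_training=5, n_control=4, seed=7)
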