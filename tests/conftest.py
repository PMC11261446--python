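import numpy as np
import pytest

from perspire.experiments import (
    droplet_statistics_experiment,
    dropwise_recovery_experiment,
)


@pytest.fixture(scope="session")
def dropwise_recovery():
    """Rendered dropwise scene pushed through the full imaging chain."""
    return dropwise_recovery_experiment(seed=3)


@pytest.fixture(scope="session")
def droplet_statistics():
    """Long truth-mask scene with several thousand droplet events."""
    return droplet_statistics_experiment(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
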