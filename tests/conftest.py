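import numpy as np
import pytest

from voxeltune.design import DesignParams, generate_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_schedule():
    """A reduced but fully counterbalanced session: 48 trials, 12 nulls."""
    params = DesignParams(trials_per_condition=12, n_null=12)
    return generate_schedule(params, np.random.default_rng(7))


@pytest.fixture(scope="session")
def full_schedule():
    """The study-scale session: 192 trials, 48 nulls."""
    return generate_schedule(DesignParams(), np.random.default_rng(11))
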