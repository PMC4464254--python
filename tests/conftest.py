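import numpy as np
import pytest
from hypothesis import settings

from riskdeck.task import generate_task_sequence

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def task180():
    """One fixed 180-trial stimulus sequence shared across tests."""
    return generate_task_sequence(180, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
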