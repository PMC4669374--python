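import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "soilpah",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("soilpah")


@pytest.fixture
def rng():
    return np.random.default_rng(20230517)


@pytest.fixture
def activity_fixture_records():
    """Printed treatment-mean tables as tidy activity records."""
    from soilpah import datasets

    return datasets.load_all_activity_tables()


@pytest.fixture
def phytotox_fixture_table():
    from soilpah import datasets

    return datasets.load_phytotox_inhibition()
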