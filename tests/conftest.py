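import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chamopt as c

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_data() -> c.Dataset:
    return c.load_design_table()


@pytest.fixture(scope="session")
def default_ensemble(fixture_data) -> c.EnsembleResult:
    """The default 20-member ensemble on the packaged dataset, shared."""
    return c.train_ensemble(fixture_data, n_nets=20, base_seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
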