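import pytest

from alertminer import make_miner
from alertminer.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def synthetic_default():
    """Default study conditions: n=500, 40% positives, 5% label noise, seed 1."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def circular_alerts(synthetic_default):
    """Alerts mined from the default synthetic dataset with the circular strategy."""
    return make_miner("circular")(synthetic_default.dataset)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small, quick dataset for pipeline-level tests."""
    return generate(SyntheticSpec(n_molecules=120, seed=7))
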