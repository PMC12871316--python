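import pytest

from segfuse import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study under default conditions, shared read-only."""
    return simulate_study(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_study():
    """A cheaper study for tests that only need structure, not statistics."""
    return simulate_study(SimConfig(seed=7, n_paralogs=3, n_reads=60))
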