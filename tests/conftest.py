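import pytest

from paleosrna.synthetic import SimulationConfig, make_references


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast configuration for unit-level simulation tests."""
    return SimulationConfig(
        seed=1,
        n_mirna_families=10,
        n_controls=3,
        reads_per_control=3000,
        reads_ancient=8000,
    )


@pytest.fixture(scope="session")
def small_references(small_config):
    return make_references(small_config)
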