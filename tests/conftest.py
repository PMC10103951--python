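import pytest

from braincirc import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    """Compact study design used by most integration-level tests."""
    return sim.SimConfig(
        n_genes=120,
        disease=sim.DiseaseConfig(n_case=10, n_control=10),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sim.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (full design, seed 0)."""
    return sim.simulate_dataset(sim.SimConfig())
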