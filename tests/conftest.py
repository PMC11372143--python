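import pytest

from seloopkit import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def genome(sim_config) -> sd.SyntheticGenome:
    return sd.generate_genome(sim_config)


@pytest.fixture(scope="session")
def chip_inputs(genome, sim_config):
    return sd.simulate_chip_inputs(genome, sim_config)


@pytest.fixture(scope="session")
def fragment_map(genome):
    return genome.fragment_map()


@pytest.fixture(scope="session")
def bait(genome):
    return sd.bait_spec_for(genome)
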