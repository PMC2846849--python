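import pytest

from mitoburden.genome import CircularGenome, load_rcrs_features
from mitoburden.simulate import GenePlan, SimulationConfig, make_cohorts, make_genome


@pytest.fixture(scope="session")
def rcrs_features():
    return load_rcrs_features()


@pytest.fixture(scope="session")
def rcrs_coords():
    """Coordinate-only rCRS genome (no sequence is shipped)."""
    return CircularGenome("rCRS-coordinates", 16569)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        seed=11,
        n_cases=8,
        n_controls=8,
        gene_plans={
            "NDA": GenePlan(p_nonsyn=0.4, p_syn=0.3),
            "COA": GenePlan(p_nonsyn=0.25, p_syn=0.25),
            "ATPA": GenePlan(p_nonsyn=0.3),
            "rrnS": GenePlan(p_insertion=0.2),
        },
    )


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return make_genome(sim_config)


@pytest.fixture(scope="session")
def sim_cohorts(sim_config, sim_genome):
    genome, features = sim_genome
    return make_cohorts(genome, features, sim_config)
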