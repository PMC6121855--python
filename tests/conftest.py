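import pytest
from hypothesis import settings

from mycocluster.core import GeneRecord, GenomeRecord, Parameters
from mycocluster.simulate import SimulationConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick, smaller dataset for unit tests that need real genomes."""
    cfg = SimulationConfig(seed=2, n_background_families=60)
    return simulate_dataset(cfg)


@pytest.fixture
def params():
    return Parameters()


def make_genome(genome_id, phenotype, gene_specs, ecology=()):
    """gene_specs: list of (scaffold, order_index, gene_id[, seq])."""
    genes = []
    for spec in gene_specs:
        scaffold, idx, gid = spec[:3]
        seq = spec[3] if len(spec) > 3 else "MKLVINSGAW"
        genes.append(GeneRecord(gene_id=gid, genome_id=genome_id,
                                scaffold_id=scaffold, order_index=idx,
                                protein_seq=seq))
    return GenomeRecord(genome_id=genome_id, genes=genes,
                        phenotype=phenotype, ecology=frozenset(ecology))
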