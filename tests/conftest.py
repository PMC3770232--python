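import pytest

from bindscan.core import Gene, GenomeAnnotation, Interval
from bindscan.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_annotation():
    """Six genes on two chromosomes, both strands, hand-placed."""
    genes = [
        Gene("geneA", Interval("chr1", 10_000, 30_000, "+")),    # tss 10000
        Gene("geneB", Interval("chr1", 42_000, 60_000, "-")),    # tss 59999
        Gene("geneC", Interval("chr1", 100_000, 140_000, "+")),  # tss 100000
        Gene("geneD", Interval("chr1", 150_000, 170_000, "-")),  # tss 169999
        Gene("geneE", Interval("chr2", 5_000, 25_000, "+")),     # tss 5000
        Gene("geneF", Interval("chr2", 40_000, 70_000, "-")),    # tss 69999
    ]
    return GenomeAnnotation({"chr1": 500_000, "chr2": 200_000, "chrEmpty": 50_000}, genes)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared read-only across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def big_noseq_config():
    """Config for expression-scale runs: 4000 genes, coordinates only."""

    def make(seed: int) -> SimulationConfig:
        return SimulationConfig(
            seed=seed,
            n_chroms=4,
            chrom_length_bp=50_000_000,
            n_genes=4000,
            n_sites=5000,
            generate_sequence=False,
        )

    return make
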