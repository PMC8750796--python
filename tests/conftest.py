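import pytest

from srnaland.core_io import Sample, SampleTable
from srnaland.locus_profiler import classify_locus, cluster_reads, expression_table_from_loci
from srnaland.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset, shared across tests (read-only)."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def called_loci(dataset):
    loci = cluster_reads(dataset.reads, dataset.samples)
    for locus in loci:
        classify_locus(locus)
    return loci


@pytest.fixture(scope="session")
def expression(dataset, called_loci):
    return expression_table_from_loci(called_loci, dataset.samples)


@pytest.fixture
def two_tissue_samples():
    """Minimal two-tissue sample table for hand-built expression tests."""
    return SampleTable(
        [
            Sample("embryo_r1", "embryo", 1, 1_000_000),
            Sample("embryo_r2", "embryo", 2, 1_000_000),
            Sample("endosperm_r1", "endosperm", 1, 1_000_000),
            Sample("endosperm_r2", "endosperm", 2, 1_000_000),
        ]
    )
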