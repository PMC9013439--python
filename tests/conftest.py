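import pytest

import tandemdup as td
from tandemdup.simulate import SimConfig, simulate_genome, write_fixture

# One moderate fixture shared across test modules: 10 genes on both
# strands, 10 planted copies at 10% substitution divergence, a third of
# them UTR-derived, 6 tissues with half the copies expressed.
BASE_CONFIG = SimConfig(
    seed=11,
    n_genes=10,
    exons_per_gene=(4, 6),
    exon_len=(60, 180),
    intron_len=(250, 700),
    intergenic_len=(500, 1200),
    n_duplications=10,
    divergence_levels=(0.10,),
    utr_fraction=0.3,
    n_tissues=6,
    expressed_fraction=0.5,
)


@pytest.fixture(scope="session")
def base_fixture():
    return simulate_genome(BASE_CONFIG)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, base_fixture):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(base_fixture, d)
    return d


@pytest.fixture(scope="session")
def genes(fixture_dir):
    return td.read_annotation(fixture_dir / "annotation.gtf")


@pytest.fixture(scope="session")
def searched_pairs(genes, base_fixture):
    return td.run_search(genes, base_fixture.genome)
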