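from hypothesis import HealthCheck, settings
import pytest

from mgsim.fixtures import build_world, write_fixture_set
from mgsim.genome_store import make_synthetic_genome
from mgsim.taxonomy_profile import TaxNode, TaxonomyTable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome_50k():
    """A 50 kb single-contig synthetic genome shared across read-sim tests."""
    return make_synthetic_genome(50_000, gc=0.45, n_contigs=1, seed=11, genome_id="g50k", taxid=1000)


@pytest.fixture(scope="session")
def world():
    """Two genera x two species with one genome each."""
    return build_world(n_genera=2, species_per_genus=2, genome_length=20_000, n_contigs=2, seed=5)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete on-disk fixture set (genomes, taxonomy, tables, config)."""
    d = tmp_path_factory.mktemp("fixtures")
    paths = write_fixture_set(d, seed=3)
    return d, paths


@pytest.fixture(scope="session")
def chain_taxonomy():
    """A single complete 7-rank lineage: root -> ... -> species 1000."""
    nodes = {
        1: TaxNode(1, "no rank", "root"),
        2: TaxNode(1, "superkingdom", "Bacteria"),
        3: TaxNode(2, "phylum", "PhylumX"),
        4: TaxNode(3, "class", "ClassX"),
        5: TaxNode(4, "order", "OrderX"),
        6: TaxNode(5, "family", "FamilyX"),
        7: TaxNode(6, "genus", "GenusX"),
        1000: TaxNode(7, "species", "GenusX speciesA"),
        1001: TaxNode(7, "species", "GenusX speciesB"),
    }
    return TaxonomyTable(nodes)
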