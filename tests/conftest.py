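"""Shared fixtures: toy graphs and a scaled-down synthetic study."""

import networkx as nx
import pytest

from gcnet.genesets import GeneSet
from gcnet.interactome import InteractionNetwork
from gcnet.synthetic import SyntheticConfig


def make_network(edges, isolated=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(isolated)
    return InteractionNetwork(graph=g)


@pytest.fixture
def path_network():
    """a - b - c."""
    return make_network([("a", "b"), ("b", "c")])


@pytest.fixture
def star_network():
    """Center c with four leaves."""
    return make_network([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def cycle_network():
    """4-cycle a - b - c - d - a."""
    return make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def gene_set_factory():
    def make(genes, name="set", species="human"):
        return GeneSet(name=name, species=species, genes=frozenset(genes))
    return make


@pytest.fixture
def small_config():
    """A fast, scaled-down synthetic study for unit tests."""
    return SyntheticConfig(
        seed=7,
        n_genes=400,
        n_annotation=150,
        n_enriched_datasets=3,
        enrichment_set_sizes=(60, 40, 50),
        mouse_dataset_indices=(1,),
        n_overlap=40,
        n_planted_consistent_up=2,
        n_planted_consistent_down=3,
        n_planted_inconsistent=2,
        core_edge_factor=3.0,
        n_phenotypes=4,
        n_phenotype_clusters=2,
        module_size=5,
    )
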