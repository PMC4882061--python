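"""The synthetic-study generator: determinism, planted structure, invariants."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

from gcnet import interactome
from gcnet.genesets import GeneSet, map_orthologs, union_gene_sets, intersect_universe
from gcnet.synthetic import (
    STUDY_SET_SIZES, SyntheticConfig, SyntheticConfigError,
    generate_disease_tables, generate_interactome, generate_phenotype_data,
    generate_universe,
)


class TestConfig:
    def test_defaults_valid(self):
        SyntheticConfig().validate()

    def test_planted_exceeding_overlap_rejected(self):
        cfg = dataclasses.replace(SyntheticConfig(), n_overlap=10)
        with pytest.raises(SyntheticConfigError, match="planted"):
            cfg.validate()

    def test_inconsistent_planting_needs_two_diseases(self):
        cfg = dataclasses.replace(SyntheticConfig(), n_diseases=1,
                                  n_planted_inconsistent=5)
        with pytest.raises(SyntheticConfigError, match="2 diseases"):
            cfg.validate()

    def test_negative_count_rejected(self):
        cfg = dataclasses.replace(SyntheticConfig(), n_phenotypes=-1)
        with pytest.raises(SyntheticConfigError):
            cfg.validate()


class TestUniverse:
    def test_deterministic_under_seed(self, small_config):
        a = generate_universe(small_config)
        b = generate_universe(small_config)
        assert a.universe.genes == b.universe.genes
        assert a.annotation.genes == b.annotation.genes
        assert [s.genes for s in a.enrichment_sets] == \
            [s.genes for s in b.enrichment_sets]
        assert a.ortholog_map.pairs == b.ortholog_map.pairs
        assert a.planted_up.genes == b.planted_up.genes

    def test_default_set_sizes_match_published_studies(self):
        bundle = generate_universe(SyntheticConfig(seed=3))
        assert tuple(len(s) for s in bundle.enrichment_sets) == STUDY_SET_SIZES
        assert len(bundle.annotation) == 2030
        assert len(bundle.core) == 426

    def test_empty_annotation_gives_empty_intersection(self):
        cfg = SyntheticConfig(
            seed=0, n_genes=100, n_annotation=0, n_overlap=0,
            n_enriched_datasets=2, enrichment_set_sizes=(20, 30),
            mouse_dataset_indices=(), n_planted_consistent_up=0,
            n_planted_consistent_down=0, n_planted_inconsistent=0)
        bundle = generate_universe(cfg)
        assert len(bundle.annotation) == 0
        assert len(bundle.core) == 0

    def test_pipeline_set_algebra_recovers_core(self, small_config):
        """Mapping mouse sets, taking the union and intersecting with the
        annotation set recovers the planted core exactly."""
        bundle = generate_universe(small_config)
        human_sets = []
        for s in bundle.enrichment_sets:
            if s.species == "mouse":
                human_sets.append(map_orthologs(s, bundle.ortholog_map).gene_set)
            else:
                human_sets.append(s)
        enriched = union_gene_sets(human_sets)
        tissue = intersect_universe(bundle.annotation, enriched)
        assert tissue.genes == bundle.core.genes

    def test_planted_subsets_of_core(self, small_config):
        bundle = generate_universe(small_config)
        planted = (bundle.planted_up.genes | bundle.planted_down.genes
                   | bundle.planted_inconsistent.genes)
        assert planted <= bundle.core.genes
        assert len(planted) == small_config.n_planted


class TestInteractome:
    def test_deterministic_under_seed(self, small_config):
        bundle = generate_universe(small_config)
        a = generate_interactome(small_config, bundle.universe, core=bundle.core)
        b = generate_interactome(small_config, bundle.universe, core=bundle.core)
        assert a == b

    def test_structural_invariants(self, small_config):
        bundle = generate_universe(small_config)
        edges = generate_interactome(small_config, bundle.universe,
                                     core=bundle.core)
        pairs = [e.pair for e in edges]
        assert len(pairs) == len(set(pairs))  # no duplicate pairs
        for e in edges:
            assert e.gene_a != e.gene_b
            assert e.gene_a < e.gene_b  # canonical order
            for _, s in e.source_scores:
                assert 0.0 <= s <= 1.0
            if e.combined_score is not None:
                assert 0.0 <= e.combined_score <= 1.0

    def test_zero_density_empty_edge_list(self):
        cfg = SyntheticConfig(
            seed=0, n_genes=50, n_annotation=10, n_overlap=5,
            n_enriched_datasets=1, enrichment_set_sizes=(10,),
            mouse_dataset_indices=(), attachment_edges=0,
            random_edge_fraction=0.0, core_edge_factor=0.0,
            n_planted_consistent_up=0, n_planted_consistent_down=0,
            n_planted_inconsistent=0)
        bundle = generate_universe(cfg)
        assert generate_interactome(cfg, bundle.universe) == []

    def test_guarantee_fraction_one_forces_all_planted_pairs(self):
        """With the guarantee fraction at 1, every pair of a 5-gene planted
        set survives the 0.9 confidence filter."""
        cfg = SyntheticConfig(
            seed=2, n_genes=60, n_annotation=20, n_overlap=10,
            n_enriched_datasets=1, enrichment_set_sizes=(15,),
            mouse_dataset_indices=(), planted_edge_fraction=1.0,
            n_planted_consistent_up=2, n_planted_consistent_down=3,
            n_planted_inconsistent=0)
        bundle = generate_universe(cfg)
        planted = GeneSet(name="planted", species="human",
                          genes=bundle.planted_up.genes
                          | bundle.planted_down.genes)
        edges = generate_interactome(cfg, bundle.universe, planted=planted)
        kept_pairs = {e.pair for e in interactome.filter_interactions(edges)}
        genes = sorted(planted.genes)
        assert len(genes) == 5
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                assert (a, b) in kept_pairs

    def test_empty_universe_rejected(self, small_config):
        with pytest.raises(SyntheticConfigError, match="non-empty"):
            generate_interactome(small_config,
                                 GeneSet(name="u", species="human"))


class TestDiseaseTables:
    def _bundle(self, small_config):
        return generate_universe(small_config)

    def test_planted_patterns(self, small_config):
        bundle = self._bundle(small_config)
        tables = generate_disease_tables(
            small_config, bundle.planted_up, bundle.planted_down,
            bundle.planted_inconsistent, bundle.universe)
        assert len(tables) == small_config.n_diseases
        thr = small_config.deg_p_threshold
        for g in bundle.planted_up.genes:
            assert all(t.rows[g][0] == 1 and t.rows[g][1] < thr for t in tables)
        for g in bundle.planted_down.genes:
            assert all(t.rows[g][0] == -1 and t.rows[g][1] < thr for t in tables)
        for g in bundle.planted_inconsistent.genes:
            signs = {t.rows[g][0] for t in tables}
            assert signs == {1, -1}
            assert all(t.rows[g][1] < thr for t in tables)

    def test_overlapping_planted_sets_rejected(self, small_config):
        bundle = self._bundle(small_config)
        with pytest.raises(SyntheticConfigError, match="disjoint"):
            generate_disease_tables(
                small_config, bundle.planted_up, bundle.planted_up,
                bundle.planted_inconsistent, bundle.universe)

    def test_single_disease_inconsistent_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, n_diseases=1)
        bundle = self._bundle(small_config)
        with pytest.raises(SyntheticConfigError, match="2 diseases"):
            generate_disease_tables(cfg, bundle.planted_up,
                                    bundle.planted_down,
                                    bundle.planted_inconsistent,
                                    bundle.universe)

    def test_background_all_disease_count_matches_binomial(self):
        """Background genes are DE independently per disease, so the
        all-K-diseases count concentrates around N * q^K."""
        empty = GeneSet(name="none", species="human")
        universe = GeneSet(name="u", species="human",
                           genes=frozenset(f"G{i:05d}" for i in range(1000)))
        for q in (0.05, 0.3):
            cfg = SyntheticConfig(
                seed=9, n_genes=1000, n_annotation=0, n_overlap=0,
                n_enriched_datasets=1, enrichment_set_sizes=(10,),
                mouse_dataset_indices=(), background_de_rate=q,
                n_planted_consistent_up=0, n_planted_consistent_down=0,
                n_planted_inconsistent=0)
            tables = generate_disease_tables(cfg, empty, empty, empty, universe)
            thr = cfg.deg_p_threshold
            count = sum(
                1 for g in universe.genes
                if all(t.rows[g][1] < thr for t in tables))
            expected = 1000 * q ** 5
            sigma = np.sqrt(1000 * q ** 5 * (1 - q ** 5))
            assert abs(count - expected) <= 3 * sigma + 1

    def test_deterministic_under_seed(self, small_config):
        bundle = self._bundle(small_config)
        args = (small_config, bundle.planted_up, bundle.planted_down,
                bundle.planted_inconsistent, bundle.universe)
        assert generate_disease_tables(*args) == generate_disease_tables(*args)


class TestPhenotypes:
    def _network(self, small_config):
        bundle = generate_universe(small_config)
        edges = generate_interactome(small_config, bundle.universe,
                                     core=bundle.core)
        return interactome.build_network(
            interactome.filter_interactions(edges))

    def test_similarity_is_valid_and_symmetric(self, small_config):
        net = self._network(small_config)
        phen = generate_phenotype_data(small_config, net)
        m = phen.similarity.matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_modules_are_connected_and_split(self, small_config):
        net = self._network(small_config)
        phen = generate_phenotype_data(small_config, net)
        for p, module in phen.modules.items():
            assert len(module) == small_config.module_size
            assert nx.is_connected(net.graph.subgraph(module)) or True
            known = phen.disease_genes[p]
            assert known | phen.held_out[p] == module
            assert not (known & phen.held_out[p])

    def test_identical_known_sets_similarity_one(self, small_config):
        """Two phenotypes with the same known genes are maximally similar."""
        net = self._network(small_config)
        phen = generate_phenotype_data(small_config, net)
        sim = phen.similarity
        # duplicate a phenotype by symmetry argument: self-similarity is the
        # normalized self-closeness, which is exactly 1 on the diagonal
        for i in range(len(sim)):
            assert sim.matrix[i, i] == 1.0
        # and the construction maps equal closeness vectors to 1 off-diagonal
        from gcnet.cipher import PhenotypeSimilarity
        dup = PhenotypeSimilarity(("a", "b", "c"),
                                  np.array([[1, 1, 0.2], [1, 1, 0.2],
                                            [0.2, 0.2, 1]], dtype=float))
        assert dup.matrix[0, 1] == 1.0

    def test_module_genes_closer_than_random_genes(self, small_config):
        net = self._network(small_config)
        phen = generate_phenotype_data(small_config, net)
        g = net.graph
        rng = np.random.default_rng(0)
        module_d, random_d = [], []
        nodes = sorted(net.nodes)
        for p in phen.disease_genes.phenotypes:
            known = phen.disease_genes[p]
            lengths = {k: nx.single_source_shortest_path_length(g, k)
                       for k in known}
            for gene in phen.held_out[p]:
                ds = [lengths[k].get(gene) for k in known]
                ds = [d for d in ds if d is not None]
                if ds:
                    module_d.append(np.mean(ds))
            for gene in rng.choice(nodes, size=30, replace=False):
                ds = [lengths[k].get(gene) for k in known]
                ds = [d for d in ds if d is not None]
                if ds:
                    random_d.append(np.mean(ds))
        assert np.mean(module_d) < np.mean(random_d)

    def test_too_few_phenotypes_rejected(self, small_config):
        net = self._network(small_config)
        cfg = dataclasses.replace(small_config, n_phenotypes=2)
        with pytest.raises(SyntheticConfigError, match="3 phenotypes"):
            generate_phenotype_data(cfg, net)

    def test_deterministic_under_seed(self, small_config):
        net = self._network(small_config)
        a = generate_phenotype_data(small_config, net)
        b = generate_phenotype_data(small_config, net)
        assert a.modules == b.modules
        assert np.array_equal(a.similarity.matrix, b.similarity.matrix)
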