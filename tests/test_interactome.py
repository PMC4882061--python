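"""Score integration, confidence filtering, induction and topology."""

import math

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from gcnet.genesets import GeneSet
from gcnet.interactome import (
    CURATED, SCORED, InteractionNetwork, ScoredInteraction, ScoreError,
    combine_scores, filter_interactions, induce_network, build_network,
    compute_degree, compute_betweenness, summarize_network,
    mean_interactions_per_node, read_interactions_tsv, write_interactions_tsv,
)
from .conftest import make_network
from .oracles import adjacency, brute_betweenness


class TestCombineScores:
    def test_single_source_below_cap_is_identity(self):
        assert combine_scores([("expA", 0.8)]) == pytest.approx(0.8)

    def test_two_sources_noisy_or(self):
        # 1 - 0.2 * 0.4
        assert combine_scores([("expA", 0.8), ("expB", 0.6)]) == pytest.approx(0.92)

    def test_single_source_capped_at_09(self):
        """One channel can never exceed the cap, so it exactly meets a >= 0.9
        threshold but can never pass a strict > 0.9 one."""
        assert combine_scores([("expA", 0.95)]) == pytest.approx(0.9)
        assert combine_scores([("expA", 1.0)]) == pytest.approx(0.9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoreError):
            combine_scores([("x", 1.2)])
        with pytest.raises(ScoreError):
            combine_scores([("x", -0.1)])

    def test_prior_correction_recovers_prior_floor(self):
        # with a prior, a channel at the prior level adds no evidence
        assert combine_scores([("x", 0.1)], prior=0.1) == pytest.approx(0.1)
        combined = combine_scores([("x", 0.6), ("y", 0.6)], prior=0.1)
        expected = (1 - (1 - 0.5 / 0.9) ** 2) * 0.9 + 0.1
        assert combined == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(scores=st.lists(st.floats(0, 1), min_size=1, max_size=5),
           bump_index=st.integers(0, 4))
    def test_monotone_order_invariant_dominates_each_channel(
            self, scores, bump_index):
        bump_index %= len(scores)
        base = combine_scores(list(enumerate(scores)))
        assert 0.0 <= base <= 1.0
        # order invariance
        assert combine_scores(list(enumerate(reversed(scores)))) == \
            pytest.approx(base)
        # dominates every capped channel
        assert base >= min(max(scores), 0.9) - 1e-12
        # monotone in each channel
        bumped = scores.copy()
        bumped[bump_index] = min(1.0, bumped[bump_index] + 0.1)
        assert combine_scores(list(enumerate(bumped))) >= base - 1e-12


class TestFilter:
    def test_threshold_is_inclusive(self):
        lo = ScoredInteraction("A", "B", combined_score=0.89)
        hi = ScoredInteraction("A", "C", combined_score=0.92)
        at = ScoredInteraction("A", "D", combined_score=0.9)
        kept = {e.pair for e in filter_interactions([lo, hi, at])}
        assert kept == {("A", "C"), ("A", "D")}

    def test_curated_edges_bypass_threshold(self):
        curated = ScoredInteraction("A", "B", database=CURATED)
        kept = filter_interactions([curated])
        assert [e.pair for e in kept] == [("A", "B")]

    def test_strict_mode_drops_unscored_curated(self):
        curated = ScoredInteraction("A", "B", database=CURATED)
        assert filter_interactions([curated], strict=True) == []

    def test_duplicate_pairs_keep_max_combined(self):
        e1 = ScoredInteraction("A", "B", combined_score=0.91)
        e2 = ScoredInteraction("B", "A", combined_score=0.95)
        kept = filter_interactions([e1, e2])
        assert len(kept) == 1
        assert kept[0].combined_score == pytest.approx(0.95)

    def test_self_interaction_rejected(self):
        with pytest.raises(ScoreError):
            ScoredInteraction("A", "A", combined_score=0.95)


class TestInduction:
    def test_empty_universe_empty_network(self):
        net = induce_network(GeneSet(name="u", species="human"), [])
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_isolated_universe_genes_retained(self):
        universe = GeneSet(name="u", species="human",
                           genes=frozenset({"A", "B", "C"}))
        edges = [ScoredInteraction("A", "B", combined_score=0.95),
                 ScoredInteraction("B", "D", combined_score=0.95)]
        net = induce_network(universe, edges)
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {("A", "B")}

    def test_filter_induce_commutes_with_induce_filter(self):
        universe = GeneSet(name="u", species="human",
                           genes=frozenset(f"G{i}" for i in range(10)))
        edges = [
            ScoredInteraction(f"G{i}", f"G{(i + 3) % 12 if (i + 3) % 12 != i else i + 1}",
                              combined_score=0.85 + 0.02 * (i % 6))
            for i in range(12)
        ]
        a = induce_network(universe, filter_interactions(edges))
        restricted = [e for e in edges
                      if e.gene_a in universe.genes and e.gene_b in universe.genes]
        b = induce_network(universe, filter_interactions(restricted))
        assert a.nodes == b.nodes and a.edges == b.edges


class TestTopology:
    def test_degree_star_and_isolated(self, star_network):
        star_network.graph.add_node("iso")
        deg = compute_degree(star_network)
        assert deg["c"] == 4 and deg["iso"] == 0
        assert all(deg[f"l{i}"] == 1 for i in range(4))

    def test_handshake_identity(self, small_config):
        import gcnet.synthetic as syn
        bundle = syn.generate_universe(small_config)
        edges = syn.generate_interactome(small_config, bundle.universe,
                                         core=bundle.core)
        net = build_network(edges)
        assert sum(compute_degree(net).values()) == 2 * net.n_edges

    def test_betweenness_path(self, path_network):
        bc = compute_betweenness(path_network)
        assert bc == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_betweenness_star(self, star_network):
        bc = compute_betweenness(star_network)
        assert bc["c"] == pytest.approx(6.0)  # C(4,2) leaf pairs

    def test_betweenness_cycle(self, cycle_network):
        bc = compute_betweenness(cycle_network)
        assert all(v == pytest.approx(0.5) for v in bc.values())

    def test_degree_le_one_has_zero_betweenness(self, path_network):
        bc = compute_betweenness(path_network)
        deg = compute_degree(path_network)
        assert all(bc[v] == 0 for v in bc if deg[v] <= 1)

    def test_betweenness_matches_enumeration_oracle_random(self):
        for seed in range(10):
            g = nx.gnm_random_graph(25, 40, seed=seed)
            net = InteractionNetwork(graph=nx.relabel_nodes(
                g, {i: f"n{i:02d}" for i in g.nodes}))
            oracle = brute_betweenness(
                adjacency(net.edges, nodes=net.nodes))
            result = compute_betweenness(net)
            for v in net.nodes:
                assert result[v] == pytest.approx(oracle[v], abs=1e-9)


class TestSummary:
    def test_empty_network(self):
        s = summarize_network(InteractionNetwork())
        assert s.n_nodes == 0 and s.mean_interactions_per_node == 0.0

    def test_single_node_conventions(self):
        s = summarize_network(make_network([], isolated=["A"]))
        assert s.lcc_node_fraction == 1.0
        assert s.lcc_edge_fraction == 1.0
        assert s.n_isolated_nodes == 1

    def test_two_disjoint_edges(self):
        s = summarize_network(make_network([("a", "b"), ("c", "d")]))
        assert s.lcc_node_fraction == 0.5
        assert s.lcc_edge_fraction == 0.5
        assert s.n_two_node_islets == 2

    def test_study_scale_mean_rounds_to_printed_value(self):
        """A 426-node, 827-edge network has 1.9 interactions per node."""
        g = nx.gnm_random_graph(426, 827, seed=0)
        s = summarize_network(InteractionNetwork(graph=g))
        assert s.n_edges == 827
        assert round(s.mean_interactions_per_node, 1) == 1.9
        assert mean_interactions_per_node(426, 827) == pytest.approx(827 / 426)

    def test_component_counts_partition_nodes(self, small_config):
        import gcnet.synthetic as syn
        bundle = syn.generate_universe(small_config)
        edges = syn.generate_interactome(small_config, bundle.universe,
                                         core=bundle.core)
        net = induce_network(bundle.core, filter_interactions(edges))
        s = summarize_network(net)
        assert s.n_isolated_nodes <= s.n_nodes
        lcc_nodes = round(s.lcc_node_fraction * s.n_nodes)
        assert lcc_nodes + s.n_isolated_nodes <= s.n_nodes


def test_interactions_tsv_round_trip(tmp_path):
    edges = [
        ScoredInteraction("A", "B", source_scores=(("ch1", 0.8), ("ch2", 0.6))),
        ScoredInteraction("C", "D", database=CURATED),
        ScoredInteraction("B", "C", combined_score=0.93, database=SCORED),
    ]
    path = tmp_path / "edges.tsv"
    write_interactions_tsv(edges, path)
    back = read_interactions_tsv(path)
    assert {e.pair for e in back} == {e.pair for e in edges}
    by_pair = {e.pair: e for e in back}
    assert by_pair[("A", "B")].combined_score == pytest.approx(0.92)
    assert by_pair[("C", "D")].database == CURATED
    assert by_pair[("C", "D")].combined_score is None
    assert dict(by_pair[("A", "B")].source_scores)["ch2"] == pytest.approx(0.6)
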