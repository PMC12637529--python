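"""Motif machinery: templates, census, matching, alignment, coverage."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemagraph.core import build_network
from nemagraph.fixtures import FixtureSpec, make_random_connectome
from nemagraph.motifs import (
    CONNECTED_TRIAD_CLASSES,
    MotifTemplate,
    alignment_of_matches,
    build_chain_template,
    chain_ffls,
    coverage,
    enumerate_ffls,
    hierarchical_alignment,
    match_template,
    role_composition,
    triad_census,
)

from conftest import (
    brute_force_monomorphisms,
    brute_force_triad_census,
    net_from_edges,
)


class TestChainTemplate:
    @pytest.mark.parametrize("length", range(1, 7))
    @pytest.mark.parametrize("mode", ["sequential", "intermediate"])
    def test_node_and_edge_counts(self, length, mode):
        t = build_chain_template(length, mode)
        assert t.n_nodes == 2 * length + 1
        assert t.n_edges == 3 * length

    def test_sequential_l3_shares_output_nodes_3_and_5(self):
        assert chain_ffls(3, "sequential") == [(1, 2, 3), (3, 4, 5), (5, 6, 7)]
        t = build_chain_template(3, "sequential")
        assert t.n_nodes == 7 and t.n_edges == 9

    def test_length_one_is_plain_ffl(self):
        for mode in ("sequential", "intermediate"):
            t = build_chain_template(1, mode)
            assert set(t.edges) == {(1, 2), (2, 3), (1, 3)}
            assert t.roles == {1: "input", 2: "intermediate", 3: "output"}

    def test_intermediate_l2_structure(self):
        assert chain_ffls(2, "intermediate") == [(1, 2, 3), (2, 4, 5)]
        t = build_chain_template(2, "intermediate")
        assert set(t.edges) == {(1, 2), (2, 3), (1, 3), (2, 4), (4, 5), (2, 5)}

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_chain_template(0, "sequential")
        with pytest.raises(ValueError):
            build_chain_template(2, "circular")

    def test_template_validation(self):
        with pytest.raises(ValueError):
            MotifTemplate(node_ids=(1, 2), edges=frozenset({(1, 1)}))
        with pytest.raises(ValueError):  # disconnected
            MotifTemplate(node_ids=(1, 2, 3), edges=frozenset({(1, 2)}))


class TestTriadCensus:
    def test_three_cycle(self, triangle_cycle_net):
        census = triad_census(triangle_cycle_net)
        assert census["030C"] == 1
        assert sum(census.values()) == 1

    def test_ffl(self, ffl_net):
        census = triad_census(ffl_net)
        assert census["030T"] == 1
        assert sum(census.values()) == 1

    def test_out_star_counted_per_node_set(self):
        net = net_from_edges([("A", "B"), ("A", "C"), ("A", "D")])
        census = triad_census(net)
        assert census["021D"] == 3
        assert sum(census.values()) == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(12, 0.25, directed=True, seed=int(rng.integers(1 << 30)))
        net = net_from_edges([(f"n{u}", f"n{v}") for u, v in g.edges])
        got = triad_census(net)
        expected = brute_force_triad_census(net.to_digraph("chemical"))
        assert got == expected

    def test_counts_sum_to_connected_triples(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        g = net.to_digraph("chemical")
        n_connected = sum(
            1 for cls in (brute_force_triad_census(g),) for v in cls.values()
        ) and sum(brute_force_triad_census(g).values())
        assert sum(triad_census(net).values()) == n_connected

    def test_too_small_network_rejected(self):
        with pytest.raises(ValueError):
            triad_census(net_from_edges([("A", "B")]))


class TestMatchTemplate:
    def test_identity_embedding_of_l3_template(self):
        t = build_chain_template(3, "sequential")
        net = net_from_edges([(f"n{u}", f"n{v}") for u, v in t.edges])
        matches = match_template(net, t)
        assert len(matches) == 1
        assert matches[0].mapping == {k: f"n{k}" for k in t.node_ids}

    def test_planted_chain_with_isolated_extras(self):
        spec = FixtureSpec(
            n_neurons=27, background_edge_prob=0.0,
            planted_chains=[(3, "sequential")], seed=1,
        )
        net, truth = make_random_connectome(spec)
        matches = match_template(net, build_chain_template(3, "sequential"))
        assert len(matches) == 1
        assert matches[0].mapping == truth["chains"][0]["mapping"]

    def test_single_ffl_has_no_l2_chain(self, ffl_net):
        assert match_template(ffl_net, build_chain_template(2, "sequential")) == []

    def test_template_larger_than_net_has_no_match(self, ffl_net):
        assert match_template(ffl_net, build_chain_template(3, "sequential")) == []

    @pytest.mark.parametrize("mode", ["sequential", "intermediate"])
    @pytest.mark.parametrize("length", [1, 2, 3])
    @pytest.mark.parametrize("seed", [11, 12])
    def test_composition_equals_brute_force_on_random_digraphs(
        self, mode, length, seed
    ):
        g = nx.gnp_random_graph(12, 0.2, directed=True, seed=seed)
        net = net_from_edges([(f"n{u}", f"n{v}") for u, v in g.edges] or [("a", "b")])
        t = build_chain_template(length, mode)
        if t.n_nodes > len(net.neurons):
            pytest.skip("template larger than random net")
        got = match_template(net, t)
        expected = brute_force_monomorphisms(
            net.to_digraph("chemical"), sorted(t.edges), list(t.node_ids)
        )
        assert len(got) == len(expected)
        assert {tuple(sorted(m.mapping.items())) for m in got} == {
            tuple(sorted(m.items())) for m in expected
        }

    def test_generic_template_falls_back_to_vf2(self):
        # 2-cycle template is not a chain; matching must still work
        t = MotifTemplate(node_ids=(1, 2), edges=frozenset({(1, 2), (2, 1)}))
        net = net_from_edges([("A", "B"), ("B", "A"), ("B", "C")])
        matches = match_template(net, t)
        assert {tuple(sorted(m.mapping.values())) for m in matches} == {("A", "B")}
        assert len(matches) == 2  # both orientations of the automorphic template

    def test_min_weight_filter(self):
        net = net_from_edges([("A", "B", 6), ("B", "C", 6), ("A", "C", 1)])
        t = build_chain_template(1, "sequential")
        assert len(match_template(net, t)) == 1
        assert match_template(net, t, min_weight=5) == []

    def test_deterministic_order(self):
        g = nx.gnp_random_graph(10, 0.3, directed=True, seed=3)
        net = net_from_edges([(f"n{u}", f"n{v}") for u, v in g.edges])
        t = build_chain_template(2, "sequential")
        a = match_template(net, t)
        b = match_template(net, t)
        assert [m.mapping for m in a] == [m.mapping for m in b]


class TestHierarchicalAlignment:
    def test_all_forward_limit(self):
        counts = hierarchical_alignment(
            [("sensory", "interneuron"), ("interneuron", "motorneuron"),
             ("sensory", "motorneuron")]
        )
        assert counts.c_forward == 3 and counts.h == 1.0

    def test_all_backward_limit(self):
        counts = hierarchical_alignment(
            [("motorneuron", "interneuron"), ("interneuron", "sensory")]
        )
        assert counts.c_backward == 2 and counts.h == -1.0

    def test_mixed_hand_case(self):
        counts = hierarchical_alignment(
            [("sensory", "interneuron"), ("sensory", "motorneuron"),
             ("motorneuron", "sensory"), ("sensory", "sensory")]
        )
        assert (counts.c_forward, counts.c_backward, counts.c_lateral) == (2, 1, 1)
        assert counts.h == pytest.approx(0.25)

    def test_undefined_when_no_tallies(self):
        counts = hierarchical_alignment([("other", "sensory")])
        assert not counts.defined and counts.h is None
        assert counts.n_excluded == 1

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["sensory", "interneuron", "motorneuron", "other"]),
                st.sampled_from(["sensory", "interneuron", "motorneuron", "other"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_h_bounded_and_tally_conserving(self, edges):
        counts = hierarchical_alignment(edges)
        total = (
            counts.c_forward + counts.c_backward + counts.c_lateral + counts.n_excluded
        )
        assert total == len(edges)
        if counts.defined:
            assert -1.0 <= counts.h <= 1.0

    def test_h_invariant_under_tally_scaling(self):
        edges = [("sensory", "interneuron"), ("motorneuron", "sensory"),
                 ("sensory", "sensory")]
        assert hierarchical_alignment(edges).h == hierarchical_alignment(edges * 5).h


class TestRolesAndCoverage:
    def test_single_match_role_distribution(self):
        spec = FixtureSpec(
            n_neurons=7, background_edge_prob=0.0,
            planted_chains=[(3, "sequential")], seed=1,
        )
        net, _ = make_random_connectome(spec)
        matches = match_template(net, build_chain_template(3, "sequential"))
        comp = role_composition(matches, net)
        assert comp[1] == {"sensory": 1.0}
        assert comp[7] == {"motorneuron": 1.0}
        for node, dist in comp.items():
            assert sum(dist.values()) == pytest.approx(1.0)

    def test_empty_match_list_rejected(self, ffl_net):
        with pytest.raises(ValueError):
            role_composition([], ffl_net)

    def test_identity_match_covers_everything(self):
        t = build_chain_template(2, "sequential")
        net = net_from_edges([(f"n{u}", f"n{v}") for u, v in t.edges])
        matches = match_template(net, t)
        cov_n, cov_e = coverage(matches, net)
        assert cov_n == set(net.neurons)
        assert cov_e == set(net.connections)

    def test_no_matches_empty_coverage(self, ffl_net):
        assert coverage([], ffl_net) == (set(), set())

    def test_overlapping_matches_counted_once(self):
        # two FFLs sharing the edge A->C
        net = net_from_edges(
            [("A", "B"), ("B", "C"), ("A", "C"), ("A", "D"), ("D", "C")]
        )
        matches = match_template(net, build_chain_template(1, "sequential"))
        assert len(matches) == 2
        cov_n, cov_e = coverage(matches, net)
        assert cov_n == {"A", "B", "C", "D"}
        assert len(cov_e) == 5

    def test_alignment_of_planted_chain_is_forward(self):
        spec = FixtureSpec(
            n_neurons=30, background_edge_prob=0.0,
            planted_chains=[(3, "sequential")], seed=2,
        )
        net, _ = make_random_connectome(spec)
        matches = match_template(net, build_chain_template(3, "sequential"))
        # chain edges: 4 forward (S->I, I->M), 5 lateral (I->I), 0 backward
        counts = alignment_of_matches(matches, net)
        assert counts.c_backward == 0
        assert counts.h == pytest.approx(4 / 9)


def test_ffl_enumeration_matches_census(ffl_net):
    g = ffl_net.to_digraph("chemical")
    assert enumerate_ffls(g) == [("A", "B", "C")]
    assert triad_census(ffl_net)["030T"] == 1
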