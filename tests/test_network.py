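"""Median-joining network construction and the rho TMRCA utility."""

import itertools

import networkx as nx
import numpy as np
import pytest

import matriline as m
from matriline.network import _median_join, quasi_medians

from oracles import all_msts, brute_force_mst_cost, dreyfus_wagner_steiner_cost, hamming


def random_treelike_haplotypes(rng, n_hap, n_sites):
    """Haplotypes evolved along a random tree, one fresh site per branch
    (no homoplasy: a perfect phylogeny)."""
    states = ["A" * n_sites]
    site = 0
    while len(states) < n_hap and site < n_sites:
        parent = states[int(rng.integers(len(states)))]
        child = parent[:site] + "T" + parent[site + 1 :]
        site += 1
        if child not in states:
            states.append(child)
    return states


class TestMsn:
    def test_two_haplotypes_single_edge(self):
        g = m.build_msn(["AAAA", "ATTA"])
        assert list(g.edges(data="weight")) == [(0, 1, 2)]

    def test_equidistant_triplet_forms_triangle(self):
        states = ["AAC", "ACA", "CAA"]  # pairwise distance 2
        g = m.build_msn(states, epsilon=0)
        assert g.number_of_edges() == 3

    def test_unique_mst_matches_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            states = ["".join(rng.choice(list("AT"), size=6)) for _ in range(4)]
            if len(set(states)) < 4:
                continue
            g = m.build_msn(states)
            msts = all_msts(states)
            union = set().union(*msts)
            assert {tuple(sorted(e)) for e in g.edges} == {tuple(sorted(e)) for e in union}
            if len(msts) == 1:
                assert g.number_of_edges() == 3

    def test_epsilon_relaxation_admits_more_edges(self):
        states = ["AAAA", "TAAA", "TTAA", "TTTA"]
        g0 = m.build_msn(states, epsilon=0)
        g2 = m.build_msn(states, epsilon=2)
        assert set(g0.edges) <= set(g2.edges)
        assert g2.number_of_edges() >= g0.number_of_edges()


class TestQuasiMedian:
    def test_majority_state_per_site(self):
        assert quasi_medians("AAT", "ATA", "ATT") == ["ATT"]

    def test_three_way_tie_spawns_variants(self):
        meds = quasi_medians("A", "C", "G")
        assert sorted(meds) == ["A", "C", "G"]

    def test_variant_cap_enforced(self):
        u, v, w = "A" * 5, "C" * 5, "G" * 5
        with pytest.raises(ValueError, match="cap"):
            quasi_medians(u, v, w)


class TestMedianJoining:
    def test_perfect_star_adds_consensus_median(self):
        states = ["TAAA", "ATAA", "AATA"]
        net = m.add_median_vectors(states)
        medians = net.median_nodes()
        assert len(medians) == 1
        assert net.graph.nodes[medians[0]]["states"] == "AAAA"
        assert net.graph.degree[medians[0]] == 3

    def test_collinear_path_needs_no_median(self):
        states = ["AAAA", "TTAA", "TTTT"]  # A on a geodesic between others
        net = m.add_median_vectors(states)
        assert net.median_nodes() == []
        assert net.total_cost == 4

    def test_cost_never_increases_across_iterations(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(3, 7))
            L = int(rng.integers(3, 9))
            states = list({"".join(rng.choice(list("AT"), size=L)) for _ in range(n)})
            if len(states) < 2:
                continue
            _, costs = _median_join(states, epsilon=0, round_cap=50)
            assert all(b <= a + 1e-9 for a, b in zip(costs, costs[1:]))

    def test_treelike_data_reach_steiner_optimum(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 15:
            states = random_treelike_haplotypes(rng, int(rng.integers(3, 6)), 8)
            if len(states) < 3:
                continue
            checked += 1
            net = m.add_median_vectors(states)
            steiner = dreyfus_wagner_steiner_cost(states, 8)
            assert net.total_cost == steiner
            # tree-like: network is a tree
            assert net.graph.number_of_edges() == net.graph.number_of_nodes() - 1

    def test_order_invariance_up_to_isomorphism(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            states = list({"".join(rng.choice(list("AT"), size=6)) for _ in range(5)})
            if len(states) < 3:
                continue
            net1 = m.add_median_vectors(states)
            order = list(rng.permutation(len(states)))
            net2 = m.add_median_vectors([states[i] for i in order])

            def canon(net):
                return {
                    frozenset((net.graph.nodes[a]["states"], net.graph.nodes[b]["states"]))
                    for a, b in net.graph.edges
                }

            assert canon(net1) == canon(net2)

    def test_every_observed_haplotype_present_and_connected(self, ref, tree):
        from matriline.simulate import aligned_from_sequences

        spec = m.SimSpec(
            reference=ref,
            demes=[m.DemeSpec("P1", "x", 15, {"V": 0.4, "D1b": 0.3, "A": 0.3})],
            theta_within=2.0,
            seed=17,
        )
        seqs, popmap, _ = m.generate_dataset(spec, tree)
        part = m.collapse_haplotypes(aligned_from_sequences(seqs))
        net = m.add_median_vectors(part)
        assert nx.is_connected(net.graph)
        assert set(net.observed_nodes()) == set(part.haplotype_ids)
        total = sum(d["size"] for _, d in net.graph.nodes(data=True))
        assert total == part.n
        for v in net.median_nodes():
            assert net.graph.degree[v] >= 2


class TestMutationSteps:
    def test_adjacent_nodes_report_edge_length(self):
        net = m.add_median_vectors(["AAAA", "ATTA"])
        assert m.mutation_steps(net, "Hap_1", "Hap_2") == 2

    def test_path_lengths_add_up(self):
        # collinear 4-node path with segment lengths 2, 3, 4
        s0 = "A" * 9
        s1 = "TT" + "A" * 7
        s2 = "TTTTT" + "A" * 4
        s3 = "T" * 9
        net = m.add_median_vectors([s0, s1, s2, s3])
        assert m.mutation_steps(net, "Hap_1", "Hap_4") == 9

    def test_node_set_separation_is_minimum_over_pairs(self):
        s0, s1, s2 = "AAAA", "TTAA", "TTTT"
        net = m.add_median_vectors([s0, s1, s2])
        assert m.mutation_steps(net, ["Hap_1", "Hap_2"], ["Hap_3"]) == 2


class TestRho:
    def test_all_samples_at_root_give_zero(self):
        from matriline.diversity import HaplotypePartition

        part = HaplotypePartition(
            haplotype_ids=["Hap_1", "Hap_2"],
            representative_states=["AAAA", "ATAA"],
            members=[["a", "b", "c"], ["d"]],
            included_sites=np.arange(1, 5),
        )
        net = m.add_median_vectors(part)
        est = m.estimate_tmrca_rho(net, "Hap_1")
        assert est.rho == pytest.approx(0.25)  # 3 samples at root, 1 one step away

    def test_star_rho_one_gives_expected_years(self):
        states = ["TAAAA", "ATAAA", "AATAA", "AAATA"]
        net = m.add_median_vectors(states)
        (root,) = net.median_nodes()
        est = m.estimate_tmrca_rho(net, root, rate=3.13e-7, L=1232)
        assert est.rho == pytest.approx(1.0)
        assert est.tmrca_years == pytest.approx(1.0 / (3.13e-7 * 1232), rel=1e-12)

    def test_rho_two_computations_agree_on_trees(self):
        rng = np.random.default_rng(5)
        states = random_treelike_haplotypes(rng, 5, 8)
        net = m.add_median_vectors(states)
        root = "Hap_1"
        est = m.estimate_tmrca_rho(net, root)
        # direct Hamming to the root states (valid on homoplasy-free trees)
        root_states = net.graph.nodes[root]["states"]
        direct = np.mean(
            [hamming(net.graph.nodes[v]["states"], root_states) for v in net.observed_nodes()]
        )
        assert est.rho == pytest.approx(direct)
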