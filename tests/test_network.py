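"""Core filter, Spearman/FDR network, and O/R incidence ratio."""

import logging
import math

import numpy as np
import pytest

from conftest import make_network, make_table
from oracles import brute_force_edges, exhaustive_expected_cross
from methanonet.errors import ValidationError
from methanonet.network import (CoreFilterParams, NetworkParams, build_network,
                                filter_core_otus, incidence_ratio,
                                network_summary, or_screen)
from methanonet.synthetic import CommunitySpec, generate_otu_table


class TestCoreFilter:
    def test_single_sample_occurrence_removed_despite_abundance(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:, 0] = 100           # ubiquitous
        counts[0, 1] = 5000          # abundant but in one sample only
        table = make_table(counts)
        kept = filter_core_otus(table, CoreFilterParams())
        assert kept.otu_ids == ["OTU0"]

    def test_strict_pooled_abundance_threshold(self):
        """At a grand total of 1e6 reads, a pooled count of 9 (9e-6) is
        below the strict > 1e-5 cut and 11 (1.1e-5) is above it."""
        counts = np.zeros((10, 3), dtype=int)
        counts[:, 0] = 99998              # filler: 999_980 total
        counts[0:3, 1] = 3                # OTU1: 9 pooled
        counts[0:3, 2] = [4, 4, 3]        # OTU2: 11 pooled
        assert counts.sum() == 10**6
        kept = filter_core_otus(make_table(counts), CoreFilterParams())
        assert kept.otu_ids == ["OTU0", "OTU2"]

    def test_permissive_params_are_identity(self):
        counts = np.random.default_rng(0).integers(1, 50, size=(6, 5))
        table = make_table(counts)
        kept = filter_core_otus(table, CoreFilterParams(0.0, 1))
        assert kept.otu_ids == table.otu_ids

    def test_idempotent(self):
        counts = np.random.default_rng(1).integers(0, 5, size=(12, 8))
        counts[:, 0] = 1000
        table = make_table(counts)
        once = filter_core_otus(table)
        twice = filter_core_otus(once)
        assert once.otu_ids == twice.otu_ids

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValidationError, match="empty table"):
            filter_core_otus(make_table(np.zeros((3, 2), dtype=int)))


class TestBuildNetwork:
    def test_perfect_monotone_pair_has_rho_one(self):
        n = 20
        counts = np.ones((n, 3), dtype=int) * 10
        counts[:, 0] = np.arange(1, n + 1) * 10
        counts[:, 1] = np.arange(1, n + 1) * 7 + 3
        table = make_table(counts)
        net = build_network(table, NetworkParams(rho_min=0.9, q_max=0.01))
        assert net.graph.has_edge("OTU0", "OTU1")
        assert net.graph["OTU0"]["OTU1"]["rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_no_positive_edge(self):
        n = 20
        counts = np.ones((n, 3), dtype=int)
        counts[:, 0] = np.arange(1, n + 1)
        counts[:, 1] = np.arange(n, 0, -1)
        counts[:, 2] = 500  # dominant filler so the first two are not a closed pair
        net = build_network(make_table(counts), NetworkParams(rho_min=0.6))
        assert not net.graph.has_edge("OTU0", "OTU1")

    def test_constant_otu_excluded_but_kept_as_node(self, caplog):
        n = 30
        rng = np.random.default_rng(2)
        counts = rng.integers(10, 100, size=(n, 4))
        counts[:, 3] = 0  # constant zero vector: undefined rank correlation
        counts[:, 0] = np.arange(1, n + 1)
        counts[:, 1] = np.arange(1, n + 1) * 2
        with caplog.at_level(logging.WARNING):
            net = build_network(make_table(counts), NetworkParams(rho_min=0.6))
        assert "constant" in caplog.text
        assert "OTU3" in net.graph.nodes
        assert all("OTU3" not in e for e in net.graph.edges)

    def test_matches_brute_force_oracle_with_planted_pair(self):
        spec = CommunitySpec.from_lineage_sizes(
            {"A": 5, "B": 5}, n_samples=50,
            planted_pairs=(("A_0", "B_0", 1.0),),
            depth_per_sample=20_000, seed=7,
        )
        table = generate_otu_table(spec)
        net = build_network(table, NetworkParams(rho_min=0.6, q_max=0.01))
        assert net.graph.has_edge("A_0", "B_0")
        rel = table.relative_abundance().to_numpy()
        expected = brute_force_edges(rel, table.otu_ids, 0.6, 0.01)
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected

    def test_fdr_monotonicity_lowering_q_never_adds_edges(self):
        spec = CommunitySpec.from_lineage_sizes(
            {"A": 6, "B": 6}, n_samples=40,
            planted_pairs=(("A_0", "B_0", 0.9), ("A_1", "B_1", 0.6)),
            depth_per_sample=20_000, seed=13,
        )
        table = generate_otu_table(spec)
        edges_at = {}
        for q in (0.2, 0.05, 0.01, 0.001):
            net = build_network(table, NetworkParams(rho_min=0.3, q_max=q))
            edges_at[q] = {frozenset(e) for e in net.graph.edges}
        assert edges_at[0.001] <= edges_at[0.01] <= edges_at[0.05] <= edges_at[0.2]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="4 samples"):
            build_network(make_table(np.ones((3, 5), dtype=int)))

    def test_exact_p_for_perfect_monotone_pair(self):
        """With 5 samples, only 2 of 120 rank permutations reach
        |rho| = 1, so the exact two-sided p is 1/60."""
        counts = np.ones((5, 3), dtype=int) * 100
        counts[:, 0] = [10, 20, 30, 40, 50]
        counts[:, 1] = [11, 22, 33, 44, 55]
        counts[:, 2] = [70, 10, 40, 20, 90]
        net = build_network(
            make_table(counts),
            NetworkParams(rho_min=0.9, q_max=0.5, p_method="exact"),
        )
        assert net.graph["OTU0"]["OTU1"]["p"] == pytest.approx(2 / 120)

    def test_exact_p_matches_scipy_permutation_test(self):
        from scipy import stats as ss
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 60, size=(6, 3))
        table = make_table(counts)
        net = build_network(
            table, NetworkParams(rho_min=0.01, q_max=0.99, p_method="exact")
        )
        rel = table.relative_abundance().to_numpy()
        for u, v, d in net.graph.edges(data=True):
            i, j = table.otu_ids.index(u), table.otu_ids.index(v)
            x = rel[:, i]
            ref = ss.permutation_test(
                (rel[:, j],),
                lambda y: ss.spearmanr(x, y).statistic,
                permutation_type="pairings", n_resamples=np.inf,
                alternative="two-sided",
            )
            assert d["p"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_p_requires_small_sample_count(self):
        counts = np.random.default_rng(0).integers(1, 50, size=(12, 4))
        with pytest.raises(ValidationError, match="10 samples"):
            build_network(make_table(counts),
                          NetworkParams(p_method="exact"))


class TestNetworkSummary:
    def test_empty_network(self):
        net = make_network({"A": "L1"}, [])
        s = network_summary(net)
        assert (s.node_count, s.edge_count) == (1, 0)

    def test_complete_graph_edge_count(self):
        nodes = {f"N{i}": "L" for i in range(8)}
        edges = [(f"N{i}", f"N{j}") for i in range(8) for j in range(i + 1, 8)]
        s = network_summary(make_network(nodes, edges))
        assert (s.node_count, s.edge_count) == (8, 28)

    def test_summary_equals_direct_enumeration(self):
        spec = CommunitySpec.from_lineage_sizes(
            {"A": 8, "B": 8, "C": 8}, n_samples=50,
            planted_pairs=(("A_0", "B_0", 1.0), ("A_1", "C_1", 0.9)),
            depth_per_sample=30_000, seed=3,
        )
        table = generate_otu_table(spec)
        net = build_network(table, NetworkParams(rho_min=0.5, q_max=0.05))
        s = network_summary(net)
        assert s.node_count == len(net.graph.nodes)
        assert s.edge_count == len(net.graph.edges)
        assert sum(s.nodes_by_lineage.values()) == s.node_count
        assert sum(s.edges_by_lineage_pair.values()) == s.edge_count
        direct = sum(
            1 for u, v in net.graph.edges
            if {net.lineage_of(u), net.lineage_of(v)} == {"A", "B"}
        )
        assert s.edges_by_lineage_pair.get(("A", "B"), 0) == direct


class TestIncidenceRatio:
    def test_worked_cross_block_example(self, cross_block_network):
        res = incidence_ratio(cross_block_network, "meth", "lineage_x",
                              null_model="analytic_er")
        assert res.observed == 16
        assert res.expected == pytest.approx(64 / 7, abs=1e-12)
        assert res.or_ratio == pytest.approx(1.75, abs=1e-12)

    def test_analytic_matches_exhaustive_enumeration(self, cross_block_network):
        res = incidence_ratio(cross_block_network, "meth", "lineage_x")
        # all graphs on 8 nodes with 16 edges, 16 cross pairs
        assert res.expected == pytest.approx(
            exhaustive_expected_cross(28, 16, 16), abs=1e-9
        )

    def test_permutation_agrees_with_analytic(self, cross_block_network):
        res = incidence_ratio(cross_block_network, "meth", "lineage_x",
                              null_model="permutation_er",
                              n_permutations=20_000, seed=5)
        assert res.expected == pytest.approx(64 / 7, abs=0.05)
        assert res.perm_p is not None and res.perm_p < 0.01

    def test_degree_preserving_null_runs_and_is_seeded(self, cross_block_network):
        a = incidence_ratio(cross_block_network, "meth", "lineage_x",
                            null_model="degree_preserving",
                            n_permutations=20, seed=3)
        b = incidence_ratio(cross_block_network, "meth", "lineage_x",
                            null_model="degree_preserving",
                            n_permutations=20, seed=3)
        assert a.expected == b.expected and a.perm_p == b.perm_p

    def test_symmetry_in_lineage_order(self, cross_block_network):
        ab = incidence_ratio(cross_block_network, "meth", "lineage_x")
        ba = incidence_ratio(cross_block_network, "lineage_x", "meth")
        assert (ab.observed, ab.expected, ab.or_ratio) == \
               (ba.observed, ba.expected, ba.or_ratio)

    def test_zero_cross_edges_gives_zero_ratio(self):
        nodes = {"A1": "a", "A2": "a", "B1": "b", "B2": "b"}
        net = make_network(nodes, [("A1", "A2"), ("B1", "B2")])
        res = incidence_ratio(net, "a", "b")
        assert res.observed == 0 and res.or_ratio == 0.0

    def test_empty_graph_flagged_undefined(self):
        net = make_network({"A": "a", "B": "b"}, [])
        res = incidence_ratio(net, "a", "b")
        assert math.isnan(res.or_ratio)

    def test_missing_lineage_is_an_error(self, cross_block_network):
        with pytest.raises(ValidationError):
            incidence_ratio(cross_block_network, "meth", "no_such_lineage")

    def test_same_lineage_is_an_error(self, cross_block_network):
        with pytest.raises(ValidationError):
            incidence_ratio(cross_block_network, "meth", "meth")


class TestOrScreen:
    def test_empty_partner_list(self, cross_block_network):
        assert or_screen(cross_block_network, ["meth"], []) == []

    def test_planted_block_ranked_first_and_retained(self):
        nodes = {f"M{i}": "meth" for i in range(4)}
        nodes.update({f"X{i}": "x" for i in range(4)})
        nodes.update({f"Y{i}": "y" for i in range(4)})
        edges = [(f"M{i}", f"X{i}") for i in range(4)] + [("Y0", "Y1")]
        net = make_network(nodes, edges)
        results = or_screen(net, ["meth"], ["x", "y"], seed=0)
        assert results[0].lineage_b == "x"
        assert results[0].retained is True
        assert results[1].retained is False

    def test_all_subrandom_partners_not_retained(self):
        nodes = {f"M{i}": "meth" for i in range(4)}
        nodes.update({f"X{i}": "x" for i in range(4)})
        # only within-group edges: every cross O/R is 0 < 1
        edges = [("M0", "M1"), ("M2", "M3"), ("X0", "X1")]
        net = make_network(nodes, edges)
        results = or_screen(net, ["meth"], ["x"], seed=0)
        assert all(r.retained is False for r in results)

    def test_determinism_under_seed(self, cross_block_network):
        a = or_screen(cross_block_network, ["meth"], ["lineage_x"],
                      null_model="permutation_er", n_permutations=200, seed=11)
        b = or_screen(cross_block_network, ["meth"], ["lineage_x"],
                      null_model="permutation_er", n_permutations=200, seed=11)
        assert a == b
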