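import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emnet import (CooccurrenceNetwork, build_network,
                   filter_by_relative_abundance, keystone_diversity_correlations,
                   multi_net, sample_subnetworks, spearman_matrix, topology,
                   zi_pi)
from conftest import three_clique_bridge_graph


def _wrap(g: nx.Graph) -> CooccurrenceNetwork:
    return CooccurrenceNetwork(g, {"r_cut": 0.6, "p_cut": 0.001}, {})


class TestAbundanceFilter:
    def test_zero_threshold_identity(self, tiny_table):
        pd.testing.assert_frame_equal(
            filter_by_relative_abundance(tiny_table, 0.0), tiny_table)

    def test_fraction_arithmetic(self):
        t = pd.DataFrame([[9999, 1]], index=["s"], columns=["a", "b"])
        assert list(filter_by_relative_abundance(t, 1e-4).columns) == ["a", "b"]
        t2 = pd.DataFrame([[19999, 1]], index=["s"], columns=["a", "b"])
        assert list(filter_by_relative_abundance(t2, 1e-4).columns) == ["a"]

    def test_matches_brute_force(self, default_dataset):
        table = default_dataset.fungal_table
        kept = filter_by_relative_abundance(table, 1e-4).shape[1]
        expected = sum(table[c].sum() / table.values.sum() >= 1e-4
                       for c in table.columns)
        assert kept == expected

    def test_all_removed_errors(self, tiny_table):
        with pytest.raises(ValueError, match="lower"):
            filter_by_relative_abundance(tiny_table, 0.99)


class TestSpearman:
    def test_monotone_pairs(self):
        t = pd.DataFrame({"up": [1, 2, 3, 4, 5], "up2": [2, 4, 6, 8, 11],
                          "down": [9, 7, 5, 3, 1]})
        rho, p = spearman_matrix(t)
        assert rho.loc["up", "up2"] == pytest.approx(1.0)
        assert rho.loc["up", "down"] == pytest.approx(-1.0)

    def test_hand_ranked_value(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        rho, p = spearman_matrix(t)
        # d^2 = 4 -> 1 - 6*4/(5*24) = 0.8
        assert rho.loc["x", "y"] == pytest.approx(0.8)
        assert rho.loc["x", "y"] == pytest.approx(
            stats.spearmanr(t["x"], t["y"]).statistic)
        # untied vectors use the exact permutation null (add-one corrected)
        from itertools import permutations as perms
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        null = [abs(np.corrcoef(x, np.array(pm))[0, 1])
                for pm in perms(range(5))]
        exact = (1 + sum(v >= 0.8 - 1e-12 for v in null)) / (len(null) + 1)
        assert p.loc["x", "y"] == pytest.approx(exact)

    def test_t_approximation_forced(self):
        t = pd.DataFrame({"x": [1., 2, 3, 4, 5], "y": [2., 1, 4, 3, 5]})
        _, p = spearman_matrix(t, p_method="t")
        assert p.loc["x", "y"] == pytest.approx(
            stats.spearmanr(t["x"], t["y"]).pvalue)

    def test_tie_correction_matches_scipy(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.integers(0, 4, size=(12, 5)))
        rho, p = spearman_matrix(t)
        sp_rho, sp_p = stats.spearmanr(t.to_numpy())
        np.testing.assert_allclose(rho.to_numpy(), sp_rho, atol=1e-12)
        np.testing.assert_allclose(p.to_numpy(), sp_p, atol=1e-10)

    def test_zero_variance_flagged(self):
        t = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]})
        rho, _ = spearman_matrix(t)
        assert np.isnan(rho.loc["a", "b"])
        assert rho.loc["a", "a"] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]}))


class TestBuildNetwork:
    def test_perfect_covariation_single_edge(self):
        t = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6], "b": [2, 4, 6, 8, 10, 12],
                          "noise": [5, 1, 4, 2, 6, 3]})
        net = build_network(t, 0.9, 0.01)
        assert net.n_edges == 1
        assert net.graph.edges["a", "b"]["sign"] == 1
        assert net.graph.edges["a", "b"]["rho"] == pytest.approx(1.0)

    def test_threshold_compliance_and_symmetry(self, default_dataset):
        table = filter_by_relative_abundance(default_dataset.fungal_table, 1e-4)
        net = build_network(table, 0.6, 0.001)
        for u, v, d in net.graph.edges(data=True):
            assert abs(d["rho"]) >= 0.6 and d["p_value"] <= 0.001
            assert u != v
            assert d["sign"] == (1 if d["rho"] > 0 else -1)

    def test_planted_blocks_enriched(self, small_sim_params):
        from emnet import planted_partition_truth, simulate_dataset
        ds = simulate_dataset(small_sim_params)
        labels = planted_partition_truth(small_sim_params)
        net = build_network(ds.bacterial_table, 0.6, 0.001)
        within = cross = 0
        for u, v in net.graph.edges:
            if labels[u] >= 0 and labels[v] >= 0:
                if labels[u] == labels[v]:
                    within += 1
                else:
                    cross += 1
        assert within > cross

    def test_empty_network_warned_not_error(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(18, 5)))
        net = build_network(t, 0.999, 1e-9)
        assert net.n_edges == 0


class TestTopology:
    def test_triangle(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        t = topology(_wrap(g))
        assert t["density"] == 1.0
        assert t["average_distance"] == 1.0
        assert np.isnan(t["assortativity"])
        assert "assortativity" in t["undefined"]

    def test_path_graph(self):
        t = topology(nx.path_graph(3))
        # distances: two pairs at 1, one pair at 2 -> 4/3
        assert t["average_distance"] == pytest.approx(4 / 3)
        # normalized betweenness: middle node 1, ends 0
        assert t["betweenness_centrality"] == pytest.approx(1 / 3)
        assert t["average_degree"] == pytest.approx(4 / 3)

    def test_star(self):
        g = nx.star_graph(3)
        for u, v in g.edges:
            g.edges[u, v]["sign"] = 1
        t = topology(g)
        assert t["assortativity"] == pytest.approx(-1.0)
        assert np.isnan(t["pos_neg_ratio"])
        assert "pos_neg_ratio" in t["undefined"]
        assert t["positive_edges"] == 3 and t["negative_edges"] == 0

    def test_edge_tally_consistent(self):
        g = nx.Graph()
        g.add_edge(0, 1, sign=1)
        g.add_edge(1, 2, sign=-1)
        t = topology(g)
        assert t["edge_num"] == t["positive_edges"] + t["negative_edges"]
        assert t["pos_neg_ratio"] == pytest.approx(1.0)

    def test_empty_graph_flagged(self):
        t = topology(nx.Graph())
        assert t["node_num"] == 0
        assert "average_distance" in t["undefined"]

    def test_sign_flip_inverts_edge_signs(self):
        # negating one taxon flips the signs of exactly its incident edges;
        # on a star whose edges are all incident to "hub" the
        # positive/negative ratio therefore inverts
        rng = np.random.default_rng(3)
        n, load = 100, 0.75
        hub = rng.normal(size=n)
        noise = np.sqrt(1 - load ** 2)
        t = pd.DataFrame({
            "hub": hub,
            "a": load * hub + noise * rng.normal(size=n),
            "b": load * hub + noise * rng.normal(size=n),
            "c": -load * hub + noise * rng.normal(size=n),
        })
        net1 = build_network(t, 0.65, 0.01)
        net2 = build_network(t.assign(hub=-t["hub"]), 0.65, 0.01)
        assert set(net1.graph.edges) == set(net2.graph.edges)
        for u, v in net1.graph.edges:
            s1 = net1.graph.edges[u, v]["sign"]
            s2 = net2.graph.edges[u, v]["sign"]
            assert (s1 == -s2) == ("hub" in (u, v))
        r1 = topology(net1)["pos_neg_ratio"]
        r2 = topology(net2)["pos_neg_ratio"]
        assert r1 == pytest.approx(1.0 / r2)


class TestSubnetworks:
    def _table_for(self, g, present: dict) -> pd.DataFrame:
        cols = sorted(g.nodes)
        return pd.DataFrame(
            [[1 if c in present[s] else 0 for c in cols]
             for s in present], index=list(present), columns=cols)

    def test_full_sample_equals_parent(self, five_node_graph):
        table = self._table_for(five_node_graph,
                                {"s": set(five_node_graph.nodes)})
        m = sample_subnetworks(_wrap(five_node_graph), table)
        assert m.loc["s", "node_num"] == 5
        assert m.loc["s", "edge_num"] == 5

    def test_empty_sample_zeros(self, five_node_graph):
        m = sample_subnetworks(_wrap(five_node_graph),
                               self._table_for(five_node_graph, {"s": set()}))
        assert (m.loc["s"] == 0).all()

    def test_manual_enumeration(self, five_node_graph):
        # induced on {a, b, e}: edges a-b, a-e; betweenness of a = 1
        m = sample_subnetworks(_wrap(five_node_graph),
                               self._table_for(five_node_graph,
                                               {"s": {"a", "b", "e"}}))
        assert m.loc["s", "node_num"] == 3
        assert m.loc["s", "edge_num"] == 2
        assert m.loc["s", "betweenness_centrality"] == pytest.approx(1 / 3)

    def test_monotone_in_present_taxa(self, five_node_graph):
        sub = self._table_for(five_node_graph, {"s": {"a", "b"}})
        sup = self._table_for(five_node_graph, {"s": {"a", "b", "c", "d"}})
        m_sub = sample_subnetworks(_wrap(five_node_graph), sub)
        m_sup = sample_subnetworks(_wrap(five_node_graph), sup)
        assert m_sup.loc["s", "node_num"] >= m_sub.loc["s", "node_num"]
        assert m_sup.loc["s", "edge_num"] >= m_sub.loc["s", "edge_num"]


class TestMultiNet:
    def test_identical_samples_zero(self):
        m = pd.DataFrame({"node_num": [3, 3], "edge_num": [2, 2],
                          "betweenness_centrality": [0.1, 0.1]})
        assert (multi_net(m) == 0).all()

    def test_two_samples_symmetric(self):
        m = pd.DataFrame({"node_num": [2, 4], "edge_num": [1, 5],
                          "betweenness_centrality": [0.0, 1.0]})
        out = multi_net(m)
        assert out.iloc[0] == pytest.approx(-out.iloc[1])

    def test_hand_z_scores(self):
        m = pd.DataFrame({"node_num": [2, 3, 4], "edge_num": [1, 3, 5],
                          "betweenness_centrality": [0.0, 0.5, 1.0]})
        out = multi_net(m)
        # every metric is perfectly linear -> z columns identical -> the
        # index equals each column's z-score
        z = (np.array([2, 3, 4]) - 3) / 1.0
        np.testing.assert_allclose(out.to_numpy(), z, atol=1e-12)

    def test_zero_mean_and_unit_sd(self, default_dataset):
        from emnet import sample_subnetworks as ssn
        from emnet import build_network as bn
        table = filter_by_relative_abundance(default_dataset.fungal_table, 1e-4)
        m = ssn(bn(table, 0.6, 0.001), default_dataset.fungal_table)
        out = multi_net(m)
        assert abs(out.mean()) < 1e-12
        for col in m.columns:
            x = m[col].to_numpy(dtype=float)
            if x.std(ddof=1) > 0:
                z = (x - x.mean()) / x.std(ddof=1)
                assert abs(z.mean()) < 1e-12
                assert z.std(ddof=1) == pytest.approx(1.0)


class TestZiPi:
    def test_all_links_inside_module(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        roles = zi_pi(g)
        assert (roles["pi"] == 0).all()
        assert (roles["zi"] == 0).all()
        assert (roles["role"] == "peripheral").all()

    def test_participation_hand_value(self):
        # node x: degree 4 with links (2, 1, 1) to three clique modules
        g = nx.Graph()
        for base, size in (("a", 4), ("b", 4), ("c", 4)):
            nodes = [f"{base}{i}" for i in range(size)]
            g.add_edges_from((u, v) for i, u in enumerate(nodes)
                             for v in nodes[i + 1:])
        g.add_edges_from([("x", "a0"), ("x", "a1"), ("x", "b0"), ("x", "c0")])
        roles = zi_pi(g)
        assert roles.loc["x", "pi"] == pytest.approx(0.625)
        assert roles.loc["x", "role"] == "connector"

    def test_boundary_goes_to_lower_category(self, five_node_graph):
        roles = zi_pi(five_node_graph, pi_cut=0.0)
        # pi == 0 exactly is NOT above the cut -> stays peripheral
        single_module = roles[roles["pi"] == 0.0]
        assert (single_module["role"].isin(["peripheral", "module hub"])).all()

    def test_needs_edges(self):
        with pytest.raises(ValueError):
            zi_pi(nx.empty_graph(3))

    def test_bridge_classified_connector(self):
        rng = np.random.default_rng(11)
        g, bridge = three_clique_bridge_graph(rng)
        roles = zi_pi(g)
        assert roles.loc[bridge, "pi"] == pytest.approx(2 / 3)
        assert roles.loc[bridge, "role"] == "connector"
        others = roles.drop(bridge)
        assert (others["role"] == "peripheral").all()


class TestKeystoneCorrelations:
    def _roles(self, taxa, roles):
        return pd.DataFrame({"role": roles}, index=pd.Index(taxa, name="taxon"))

    def test_taxon_tracking_richness(self):
        rng = np.random.default_rng(0)
        richness = np.arange(10, 28).astype(float)
        table = pd.DataFrame({
            "key": richness,
            "other": np.full(18, 50.0) + rng.normal(0, 1, 18),
        }, index=[f"s{i}" for i in range(18)])
        ind = pd.DataFrame({"plant_richness": richness}, index=table.index)
        out = keystone_diversity_correlations(
            self._roles(["key"], ["connector"]), table, ind)
        row = out[(out.taxon == "key")
                  & (out.indicator == "plant_richness")].iloc[0]
        assert row["rho"] > 0.99

    def test_constant_keystone_flagged(self):
        table = pd.DataFrame({"key": [5.0] * 6, "bulk": [1, 2, 3, 4, 5, 6]},
                             index=list("abcdef"))
        # relative abundance of "key" varies only through "bulk"; make the
        # indicator constant instead to force the undefined branch
        ind = pd.DataFrame({"flat": [1.0] * 6}, index=table.index)
        out = keystone_diversity_correlations(
            self._roles(["key"], ["module hub"]), table, ind)
        assert out.iloc[0]["undefined"]

    def test_empty_keystone_set(self, tiny_table):
        out = keystone_diversity_correlations(
            self._roles(["t1"], ["peripheral"]), tiny_table,
            pd.DataFrame({"x": [1, 2]}, index=tiny_table.index))
        assert len(out) == 0
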