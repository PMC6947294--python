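"""Network filtering, cluster quality, degree-age correlation,
age assortativity (with jack-knife sigma) and |dPAI| by distance."""

import math

import networkx as nx
import numpy as np
import pytest

from phylostress.network_analysis import (
    age_assortativity,
    cluster_quality,
    degree_age_correlation,
    dpai_by_distance,
    filter_network,
    greedy_modularity_clusters,
    node_audit,
)


def net_from(edges, ages, **kw):
    return filter_network(edges, ages, **kw)


class TestFilterNetwork:
    def test_threshold_inclusive_by_default(self):
        edges = [("a", "b", 0.6), ("a", "c", 0.7), ("b", "c", 0.71),
                 ("c", "d", 0.9), ("a", "d", 0.3)]
        ages = dict.fromkeys("abcd", 1)
        net = net_from(edges, ages)
        assert net.n_edges == 3

    def test_strict_gt_flag(self):
        edges = [("a", "b", 0.7), ("a", "c", 0.8)]
        net = net_from(edges, dict.fromkeys("abc", 0), strict_gt=True)
        assert net.n_edges == 1

    def test_all_below_threshold_drop_isolated_empty(self):
        net = net_from([("a", "b", 0.2)], {"a": 0, "b": 1})
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_isolated_nodes_kept_when_requested(self):
        net = net_from([("a", "b", 0.2)], {"a": 0, "b": 1}, drop_isolated=False)
        assert net.n_nodes == 2

    def test_threshold_zero_keeps_everything(self):
        edges = [("a", "b", 0.1), ("b", "c", 0.0)]
        net = net_from(edges, dict.fromkeys("abc", 0), threshold=0.0)
        assert net.n_edges == 2

    def test_node_audit(self):
        net = net_from([("a", "b", 0.9)], {"a": 0, "b": 1, "c": 2})
        audit = node_audit(net, ["a", "b", "c", "z"])
        assert audit["dropped"] == ["c", "z"] and audit["retained"] == 2


class TestClusterQuality:
    def test_triangle_plus_pendant_hand_counts(self):
        edges = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1), ("c", "d", 1)]
        net = net_from(edges, dict.fromkeys("abcd", 0),
                       clusters={"a": "k", "b": "k", "c": "k", "d": "other"})
        q = cluster_quality(net, "k")
        assert q.deg_int == pytest.approx(2.0)
        assert q.deg_ext == pytest.approx(1 / 3)
        assert q.k_net == pytest.approx(2.0)

    def test_whole_graph_cluster_conserves_mean_degree(self):
        edges = [("a", "b", 1), ("b", "c", 1)]
        net = net_from(edges, dict.fromkeys("abc", 0),
                       clusters=dict.fromkeys("abc", "all"))
        q = cluster_quality(net, "all")
        assert q.deg_int == pytest.approx(q.k_net)
        assert q.deg_ext == 0.0

    def test_unknown_cluster_raises(self):
        net = net_from([("a", "b", 1)], {"a": 0, "b": 0}, clusters={"a": "x", "b": "x"})
        with pytest.raises(KeyError):
            cluster_quality(net, "nope")

    def test_edge_conservation_over_partition(self):
        rng = np.random.default_rng(4)
        g = nx.gnm_random_graph(20, 40, seed=2)
        edges = [(u, v, 0.9) for u, v in g.edges]
        ages = {n: int(rng.integers(0, 5)) for n in g.nodes}
        net = net_from(edges, ages)
        labels = greedy_modularity_clusters(net)
        net.clusters = labels
        internal_half = sum(
            cluster_quality(net, lab).deg_int
            * sum(1 for v in labels.values() if v == lab)
            for lab in set(labels.values())
        ) / 2
        boundary_once = sum(
            cluster_quality(net, lab).deg_ext
            * sum(1 for v in labels.values() if v == lab)
            for lab in set(labels.values())
        ) / 2
        assert internal_half + boundary_once == pytest.approx(net.n_edges)


class TestDegreeAgeCorrelation:
    def test_perfect_anticorrelation(self):
        # star-ish path: degrees (1,2,3) against ages (2,1,0)
        edges = [("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("c", "e", 1)]
        ages = {"a": 2, "b": 1, "c": 0, "d": 3, "e": 3}
        net = net_from(edges, ages)
        sub = net_from([("a", "b", 1), ("b", "c", 1), ("c", "d", 1)],
                       {"a": 2, "b": 1, "c": 1, "d": 2})
        # direct hand case: k = (1,2,2,1), pai = (2,1,1,2) -> r = -1
        assert degree_age_correlation(sub).r == pytest.approx(-1.0)

    def test_null_networks_give_small_r(self):
        rng = np.random.default_rng(0)
        rs = []
        for i in range(30):
            g = nx.gnm_random_graph(40, 80, seed=i)
            ages = {n: int(rng.integers(0, 10)) for n in g.nodes}
            net = net_from([(u, v, 1.0) for u, v in g.edges], ages)
            rs.append(degree_age_correlation(net).r)
        assert abs(np.mean(rs)) < 2 / math.sqrt(40)

    def test_too_small_or_constant_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            degree_age_correlation(net_from([("a", "b", 1)], {"a": 0, "b": 1}))
        const = net_from([("a", "b", 1), ("b", "c", 1), ("c", "a", 1)],
                         dict.fromkeys("abc", 2))
        with pytest.raises(ValueError, match="constant"):
            degree_age_correlation(const)


class TestAgeAssortativity:
    def test_perfectly_assortative(self):
        net = net_from([("a", "b", 1), ("c", "d", 1)],
                       {"a": 0, "b": 0, "c": 1, "d": 1})
        assert age_assortativity(net).r_a == pytest.approx(1.0)

    def test_path_hand_value(self):
        net = net_from([("a", "b", 1), ("b", "c", 1)], {"a": 0, "b": 0, "c": 1})
        assert age_assortativity(net).r_a == pytest.approx(-1 / 3)

    def test_perfectly_disassortative(self):
        net = net_from([("a", "b", 1), ("c", "d", 1)],
                       {"a": 0, "b": 1, "c": 1, "d": 0})
        assert age_assortativity(net).r_a == pytest.approx(-1.0)

    def test_constant_age_undefined(self):
        net = net_from([("a", "b", 1)], {"a": 2, "b": 2})
        res = age_assortativity(net)
        assert not res.defined and math.isnan(res.r_a)

    def test_single_edge_sigma_undefined(self):
        net = net_from([("a", "b", 1)], {"a": 0, "b": 1})
        res = age_assortativity(net)
        assert math.isnan(res.sigma) and res.n_pairs == 1

    def test_matches_networkx_on_atlas_graphs(self):
        """Exhaustive sweep of the small-graph atlas (<= 6 nodes): the
        directed-edge-end Pearson must match the independent mixing-matrix
        route of networkx.numeric_assortativity_coefficient."""
        from networkx.generators.atlas import graph_atlas_g

        rng = np.random.default_rng(12)
        checked = 0
        for g in graph_atlas_g():
            if g.number_of_nodes() > 6 or g.number_of_edges() < 2:
                continue
            ages = {n: int(rng.integers(0, 4)) for n in g.nodes}
            ends = [x for u, v in g.edges for x in (ages[u], ages[v])]
            if len(set(ends)) < 2:
                continue
            net = net_from([(u, v, 1.0) for u, v in g.edges], ages)
            mine = age_assortativity(net).r_a
            ref = nx.numeric_assortativity_coefficient(net.graph, "pai")
            assert mine == pytest.approx(ref, abs=1e-10)
            checked += 1
        assert checked > 100

    def test_jackknife_sigma_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        g = nx.gnm_random_graph(12, 20, seed=5)
        ages = {n: int(rng.integers(0, 6)) for n in g.nodes}
        net = net_from([(u, v, 1.0) for u, v in g.edges], ages)
        res = age_assortativity(net)
        # independent recomputation of the jack-knife sum
        edges = list(net.graph.edges)
        total = 0.0
        for i in range(len(edges)):
            sub = nx.Graph(edges[:i] + edges[i + 1 :])
            ends_x = np.array([ages[u] for u, v in sub.edges for _ in (0, 1)], float)
            xs, ys = [], []
            for u, v in sub.edges:
                xs += [ages[u], ages[v]]
                ys += [ages[v], ages[u]]
            r_i = np.corrcoef(xs, ys)[0, 1]
            if not math.isnan(r_i):
                total += (r_i - res.r_a) ** 2
        assert res.sigma == pytest.approx(math.sqrt(total))


class TestDpaiByDistance:
    def test_path_hand_bfs(self):
        net = net_from([("a", "b", 1), ("b", "c", 1)], {"a": 0, "b": 0, "c": 5})
        d = dpai_by_distance(net)
        assert d[1] == {0: 1, 5: 1}
        assert d[2] == {5: 1}
        assert sum(d[">=3"].values()) == 0

    def test_same_age_concentrates_at_zero(self):
        g = nx.path_graph(5)
        net = net_from([(u, v, 1.0) for u, v in g.edges], dict.fromkeys(g.nodes, 3))
        d = dpai_by_distance(net)
        for counter in d.values():
            assert set(counter) <= {0}

    def test_disconnected_components_excluded(self):
        net = net_from([("a", "b", 1), ("c", "d", 1)],
                       {"a": 0, "b": 1, "c": 2, "d": 3})
        d = dpai_by_distance(net)
        total_pairs = sum(sum(c.values()) for c in d.values())
        assert total_pairs == 2  # only within-component pairs

    def test_pair_count_identity(self):
        rng = np.random.default_rng(9)
        g = nx.gnm_random_graph(15, 20, seed=1)
        ages = {n: int(rng.integers(0, 5)) for n in g.nodes}
        net = net_from([(u, v, 1.0) for u, v in g.edges], ages)
        d = dpai_by_distance(net)
        total = sum(sum(c.values()) for c in d.values())
        expected = sum(
            len(comp) * (len(comp) - 1) // 2
            for comp in nx.connected_components(net.graph)
        )
        assert total == expected
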