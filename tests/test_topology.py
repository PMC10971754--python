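import functools

import networkx as nx
import numpy as np
import pytest

from coocnet.datatypes import SignedNetwork, TopologyRecord
from coocnet.topology import (
    average_path_length,
    clustering_coefficient,
    edge_counts,
    heterogeneity,
    hub_scores,
    hub_taxa,
    modularity_louvain,
    signed_neighbors,
    topology_record,
)


def signed_net(edges, nodes=None):
    if nodes is None:
        nodes = sorted({t for pair in edges for t in pair})
    return SignedNetwork(nodes=list(nodes), edges=dict(edges))


# ---------------------------------------------------------------- oracles

def brute_average_path_length(g):
    """Floyd-Warshall over reachable unordered pairs."""
    nodes = list(g.nodes)
    n = len(nodes)
    INF = float("inf")
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    idx = {v: i for i, v in enumerate(nodes)}
    for u, v in g.edges():
        d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    dists = [d[i][j] for i in range(n) for j in range(i + 1, n) if d[i][j] < INF]
    return sum(dists) / len(dists) if dists else None


def brute_transitivity(g):
    nodes = list(g.nodes)
    triangles = triples = 0
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            for k, c in enumerate(nodes):
                if len({i, j, k}) < 3:
                    continue
                if g.has_edge(a, b) and g.has_edge(b, c):
                    triples += 1  # path a-b-c centred at b, ordered
                    if g.has_edge(a, c):
                        triangles += 1
    return triangles / triples if triples else 0.0


def brute_heterogeneity(g):
    degs = [d for _, d in g.degree()]
    mean = sum(degs) / len(degs)
    if mean == 0:
        return 0.0
    var = sum((d - mean) ** 2 for d in degs) / len(degs)
    return var**0.5 / mean


def brute_max_modularity(g):
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    nodes = list(g.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {first}] + part[i + 1:]
            yield part + [{first}]

    best = 0.0
    for part in partitions(nodes):
        best = max(best, nx.community.modularity(g, part, weight=None))
    return best


def brute_hub_scores(g):
    """Independent route: long power iteration on a positive-definite shift."""
    nodes = list(g.nodes)
    if g.number_of_edges() == 0:
        return {t: 0.0 for t in nodes}
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    m = a + (a.sum(axis=1).max() + 1.0) * np.eye(len(nodes))
    x = np.ones(len(nodes))
    x /= np.linalg.norm(x)
    for _ in range(100_000):
        y = m @ x
        y /= np.linalg.norm(y)
        if np.abs(y - x).max() < 1e-13:
            x = y
            break
        x = y
    x = np.abs(x)
    x /= x.max()
    x[x < 1e-6] = 0.0
    return {t: s for t, s in zip(nodes, x)}


# ------------------------------------------------------------ hand values

class TestEdgeCounts:
    def test_ratio(self):
        edges = {(f"p{i}", f"q{i}"): 1.0 for i in range(10)}
        edges.update({(f"m{i}", f"n{i}"): -1.0 for i in range(5)})
        total, pos, neg, ratio = edge_counts(signed_net(edges))
        assert (total, pos, neg, ratio) == (15, 10, 5, 2.0)

    def test_empty(self):
        total, pos, neg, ratio = edge_counts(signed_net({}, nodes=["a"]))
        assert (total, pos, neg, ratio) == (0, 0, 0, None)

    def test_no_negatives_ratio_missing(self):
        edges = {(f"a{i}", f"b{i}"): 0.5 for i in range(4)}
        total, pos, neg, ratio = edge_counts(signed_net(edges))
        assert (total, pos, neg) == (4, 4, 0)
        assert ratio is None


class TestAveragePathLength:
    def test_path_graph(self):
        assert average_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_complete_graph(self):
        assert average_path_length(nx.complete_graph(5)) == pytest.approx(1.0)

    def test_two_disconnected_edges(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert average_path_length(g) == pytest.approx(1.0)

    def test_no_reachable_pairs(self):
        g = nx.empty_graph(3)
        assert average_path_length(g) is None


class TestHeterogeneity:
    def test_regular_graph_zero(self):
        assert heterogeneity(nx.cycle_graph(6)) == 0.0

    def test_star_hand_value(self):
        assert heterogeneity(nx.star_graph(4)) == pytest.approx(0.75)

    def test_isolated_node_increases(self):
        g = nx.cycle_graph(6)
        h0 = heterogeneity(g)
        g.add_node("iso")
        assert heterogeneity(g) > h0


class TestModularity:
    def test_two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part, q = modularity_louvain(g, seed=0)
        assert q == pytest.approx(0.5)
        assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_single_community(self):
        _, q = modularity_louvain(nx.complete_graph(4), seed=0)
        assert q == pytest.approx(brute_max_modularity(nx.complete_graph(4)))
        assert q == pytest.approx(0.0)

    def test_never_below_trivial_partition(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1e6)))
            _, q = modularity_louvain(g, seed=1)
            assert q >= 0.0

    def test_edgeless_convention(self):
        _, q = modularity_louvain(nx.empty_graph(4), seed=0)
        assert q == 0.0

    def test_best_of_restarts_non_decreasing(self):
        g = nx.gnp_random_graph(40, 0.1, seed=7)
        qs = [modularity_louvain(g, n_restarts=r, seed=0)[1] for r in (1, 5, 10)]
        assert qs[0] <= qs[1] <= qs[2]


class TestClustering:
    def test_triangle(self):
        assert clustering_coefficient(nx.complete_graph(3)) == 1.0

    def test_star(self):
        assert clustering_coefficient(nx.star_graph(5)) == 0.0

    def test_random_fixture_matches_brute_force(self):
        g = nx.gnp_random_graph(20, 0.25, seed=3)
        assert clustering_coefficient(g) == pytest.approx(brute_transitivity(g))


class TestHubScores:
    def test_complete_graph_all_ones(self):
        scores = hub_scores(nx.complete_graph(5)).scores
        assert all(s == pytest.approx(1.0) for s in scores.values())

    def test_star_hand_value(self):
        scores = hub_scores(nx.star_graph(4)).scores
        assert scores[0] == pytest.approx(1.0)
        for leaf in range(1, 5):
            assert scores[leaf] == pytest.approx(0.5)

    def test_relabelling_invariance(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        mapping = {v: f"node{v}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        s_g = hub_scores(g).scores
        s_h = hub_scores(h).scores
        for v in g.nodes:
            assert s_h[mapping[v]] == pytest.approx(s_g[v], abs=1e-9)

    def test_isolated_nodes_zero_max_one(self):
        g = nx.Graph([(0, 1), (1, 2)])
        g.add_node(99)
        scores = hub_scores(g).scores
        assert scores[99] == 0.0
        assert max(scores.values()) == pytest.approx(1.0)


class TestHubTaxa:
    def test_boundary(self):
        report = hub_scores(nx.complete_graph(2))
        report.scores = {"a": 1.0, "b": 0.5, "c": 0.49}
        assert hub_taxa(report) == ["a", "b"]

    def test_empty_network(self):
        assert hub_taxa(hub_scores(nx.empty_graph(3))) == []

    def test_star_all_leaves_qualify(self):
        report = hub_scores(nx.star_graph(4))
        assert hub_taxa(report) == [0, 1, 2, 3, 4]


class TestSignedNeighbors:
    def test_partition_by_sign(self):
        net = signed_net({("m", "w"): 0.5, ("a", "m"): -0.2})
        pos, neg = signed_neighbors(net, "m")
        assert (pos, neg) == (["w"], ["a"])

    def test_isolated(self):
        net = signed_net({("a", "b"): 1.0}, nodes=["a", "b", "c"])
        assert signed_neighbors(net, "c") == ([], [])

    def test_unknown_taxon(self):
        net = signed_net({("a", "b"): 1.0})
        with pytest.raises(KeyError):
            signed_neighbors(net, "zz")

    def test_agrees_with_edge_frame(self):
        net = signed_net(
            {("a", "b"): 1.0, ("a", "c"): -1.0, ("b", "c"): 1.0, ("a", "d"): 0.3}
        )
        df = net.edge_frame()
        rows = df[(df.taxon_i == "a") | (df.taxon_j == "a")]
        pos = sorted(
            ({r.taxon_i, r.taxon_j} - {"a"}).pop()
            for r in rows.itertuples() if r.sign == "+"
        )
        neg = sorted(
            ({r.taxon_i, r.taxon_j} - {"a"}).pop()
            for r in rows.itertuples() if r.sign == "-"
        )
        assert signed_neighbors(net, "a") == (pos, neg)


class TestRecordInvariants:
    def test_sign_counts_must_balance(self):
        with pytest.raises(ValueError):
            TopologyRecord(
                total_nodes=3, total_edges=3, positive_edges=1, negative_edges=1,
                pos_neg_ratio=1.0, average_path_length=1.0, heterogeneity=0.0,
                modularity=0.0, average_degree=2.0, clustering_coefficient=0.0,
            )

    def test_record_from_network(self):
        net = signed_net({("a", "b"): 1.0, ("b", "c"): -0.5})
        rec = topology_record(net)
        assert rec.total_edges == 2
        assert rec.positive_edges == 1
        assert rec.negative_edges == 1
        assert rec.average_degree == pytest.approx(4 / 3)


class TestOracleEquivalenceSample:
    """Spot-check all measures against independent oracles on random graphs
    (the exhaustive <=7-node sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(6))
    def test_random_graph(self, seed):
        g = nx.gnp_random_graph(7, 0.4, seed=seed)
        apl = average_path_length(g)
        b_apl = brute_average_path_length(g)
        if apl is None:
            assert b_apl is None
        else:
            assert apl == pytest.approx(b_apl)
        assert clustering_coefficient(g) == pytest.approx(brute_transitivity(g))
        assert heterogeneity(g) == pytest.approx(brute_heterogeneity(g))
        _, q = modularity_louvain(g, seed=0)
        assert q == pytest.approx(brute_max_modularity(g))
        scores = hub_scores(g).scores
        oracle = brute_hub_scores(g)
        for v in g.nodes:
            assert scores[v] == pytest.approx(oracle[v], abs=1e-5)
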