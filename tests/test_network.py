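import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import twignet as tn
from _graph_oracles import (
    _adj,
    _net_from_edges,
    _oracle_best_partition,
    _oracle_metrics,
)


# ------------------------------------------------------- spearman + build

def test_spearman_rank_invariance(plot_table):
    df = pd.DataFrame({"x": np.arange(1.0, 11), "y": np.exp(np.arange(10.0)), "z": -np.arange(10.0)})
    rho, p = tn.spearman_matrix(df, traits=["x", "y", "z"])
    assert rho.loc["x", "y"] == pytest.approx(1.0)
    assert rho.loc["x", "z"] == pytest.approx(-1.0)
    assert np.allclose(rho, rho.T)
    assert np.allclose(np.diag(rho), 1.0)


def test_spearman_tied_sample_matches_rank_covariance():
    """6-point sample with ties vs the explicit rank-covariance formula."""
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
    y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 6.0])
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    expected = np.cov(rx, ry)[0, 1] / np.sqrt(np.cov(rx, rx)[0, 1] * np.cov(ry, ry)[0, 1])
    rho, _ = tn.spearman_matrix(pd.DataFrame({"x": x, "y": y}), traits=["x", "y"])
    assert rho.loc["x", "y"] == pytest.approx(expected)


def test_spearman_constant_column_flagged_and_excluded():
    df = pd.DataFrame({"x": np.arange(6.0), "y": np.arange(6.0) ** 2, "c": np.ones(6)})
    rho, p = tn.spearman_matrix(df, traits=["x", "y", "c"])
    assert np.isnan(rho.loc["x", "c"]) and np.isnan(p.loc["c", "y"])
    net = tn.build_ptn(rho, p, alpha=0.05)
    assert "c" in net.graph.nodes
    assert net.graph.degree["c"] == 0


def test_spearman_requires_rows():
    with pytest.raises(ValueError):
        tn.spearman_matrix(pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]}), traits=["x", "y"])


def test_build_ptn_edge_filter():
    names = list("abcd")
    rho = pd.DataFrame(np.ones((4, 4)), index=names, columns=names)
    p = pd.DataFrame(np.ones((4, 4)), index=names, columns=names)
    for a, b in [("a", "b"), ("b", "c"), ("a", "d")]:
        p.loc[a, b] = p.loc[b, a] = 0.01
    rho.loc["a", "d"] = rho.loc["d", "a"] = -0.9
    net = tn.build_ptn(rho, p, alpha=0.05)
    assert net.n_edges == 3
    assert net.graph.edges[("a", "d")]["sign"] == "negative"
    assert net.graph.edges[("a", "b")]["sign"] == "positive"
    # all p >= alpha -> empty network
    empty = tn.build_ptn(rho, pd.DataFrame(np.ones((4, 4)), index=names, columns=names))
    assert empty.n_edges == 0
    with pytest.raises(ValueError):
        tn.build_ptn(rho, p, alpha=1.5)


# ----------------------------------------------------------- centralities

def test_path_graph_betweenness():
    net = _net_from_edges("abc", [("a", "b"), ("b", "c")])
    cent = tn.node_centralities(net).set_index("trait")
    assert cent.loc["b", "betweenness"] == 1.0
    assert cent.loc["a", "betweenness"] == 0.0
    assert cent.loc["c", "betweenness"] == 0.0


def test_complete_graph_centralities_and_topology():
    nodes = [f"t{i:02d}" for i in range(17)]
    net = _net_from_edges(nodes, itertools.combinations(nodes, 2))
    cent = tn.node_centralities(net)
    assert (cent["degree"] == 16).all()
    assert (cent["betweenness"] == 0).all()
    assert (cent["clustering"] == 1.0).all()
    rep = tn.topology_report(net)
    assert rep.edge_number == 136
    assert rep.edge_density == 1.0
    assert rep.connectedness == 1.0
    assert rep.average_path_length == 1.0
    assert rep.degree_centralization == 0.0
    assert rep.average_degree == 16.0
    parts, q = tn.detect_communities(net)
    assert len(parts) == 1 and q == pytest.approx(0.0)


def test_two_disjoint_triangles():
    edges = [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    net = _net_from_edges("abcdef", edges)
    rep = tn.topology_report(net)
    assert rep.connectedness == pytest.approx(6 / 15)
    parts, q = tn.detect_communities(net)
    assert q == pytest.approx(0.5)
    assert sorted(map(sorted, parts)) == [["a", "b", "c"], ["d", "e", "f"]]
    parts_x, q_x = tn.detect_communities(net, method="exact")
    assert q_x == pytest.approx(0.5)
    # exhaustive partition search confirms 0.5 is optimal
    assert _oracle_best_partition(_adj("abcdef", edges), "abcdef") == pytest.approx(0.5)


def test_empty_graph_degenerate_report():
    net = _net_from_edges("abcde", [])
    rep = tn.topology_report(net)
    assert rep.degenerate
    assert rep.edge_density == 0.0
    assert rep.connectedness == 0.0
    assert math.isnan(rep.average_path_length)
    assert math.isnan(rep.modularity)


def test_star_graph_key_trait_and_centralization():
    edges = [("SM", x) for x in ("a", "b", "c", "d")]
    net = _net_from_edges(["SM", "a", "b", "c", "d"], edges)
    ranked, key = tn.key_traits(tn.node_centralities(net))
    assert key == ["SM"]
    assert ranked[0] == "SM"
    assert tn.topology_report(net).degree_centralization == pytest.approx(1.0)


def test_key_traits_symmetric_complete_graph():
    nodes = [f"t{i:02d}" for i in range(17)]
    net = _net_from_edges(nodes, itertools.combinations(nodes, 2))
    ranked, key = tn.key_traits(tn.node_centralities(net))
    assert ranked == sorted(nodes)
    assert key == sorted(nodes)


@pytest.mark.parametrize("seed", range(10))
def test_er_graphs_match_brute_force_oracle(seed):
    """Centralities and whole-graph metrics equal independent brute-force
    computation (simple-path enumeration) on random graphs of <= 7 nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    nodes = [chr(97 + i) for i in range(n)]
    edges = [e for e in itertools.combinations(nodes, 2) if rng.random() < 0.4]
    net = _net_from_edges(nodes, edges)
    adj = _adj(nodes, edges)
    oracle = _oracle_metrics(adj, nodes)
    cent = tn.node_centralities(net).set_index("trait")
    for v in nodes:
        assert cent.loc[v, "degree"] == oracle["degree"][v]
        assert cent.loc[v, "betweenness"] == pytest.approx(oracle["betweenness"][v])
        assert cent.loc[v, "clustering"] == pytest.approx(oracle["clustering"][v])
    rep = tn.topology_report(net)
    assert rep.edge_density == pytest.approx(oracle["edge_density"])
    assert rep.connectedness == pytest.approx(oracle["connectedness"])
    if not math.isnan(oracle["average_path_length"]):
        assert rep.average_path_length == pytest.approx(oracle["average_path_length"])
    assert rep.degree_centralization == pytest.approx(oracle["centralization"])


@pytest.mark.parametrize("seed", range(8))
def test_greedy_modularity_close_to_exhaustive_optimum(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(5, 9))
    nodes = [chr(97 + i) for i in range(n)]
    edges = [e for e in itertools.combinations(nodes, 2) if rng.random() < 0.35]
    if not edges:
        return
    net = _net_from_edges(nodes, edges)
    q_best = _oracle_best_partition(_adj(nodes, edges), nodes)
    _, q_default = tn.detect_communities(net)
    assert q_default == pytest.approx(q_best, abs=0.02)
    # the greedy heuristic never exceeds the optimum
    _, q_greedy = tn.detect_communities(net, method="greedy")
    assert q_greedy <= q_best + 1e-9


def test_exact_communities_match_partition_enumeration():
    rng = np.random.default_rng(42)
    nodes = list("abcdef")
    edges = [e for e in itertools.combinations(nodes, 2) if rng.random() < 0.5]
    net = _net_from_edges(nodes, edges)
    _, q = tn.detect_communities(net, method="exact")
    assert q == pytest.approx(_oracle_best_partition(_adj(nodes, edges), nodes))


def test_metrics_invariant_to_column_permutation(plot_table):
    rho1, p1 = tn.spearman_matrix(plot_table)
    shuffled = plot_table[list(plot_table.columns[::-1])]
    rho2, p2 = tn.spearman_matrix(shuffled)
    net1 = tn.build_ptn(rho1, p1)
    net2 = tn.build_ptn(rho2, p2)
    rep1, rep2 = tn.topology_report(net1), tn.topology_report(net2)
    assert rep1.edge_number == rep2.edge_number
    assert rep1.modularity == pytest.approx(rep2.modularity)
    assert tn.key_traits(tn.node_centralities(net1)) == tn.key_traits(tn.node_centralities(net2))


def test_adding_an_edge_is_monotone():
    rng = np.random.default_rng(3)
    nodes = list("abcdef")
    edges = [("a", "b"), ("c", "d")]
    net = _net_from_edges(nodes, edges)
    rep = tn.topology_report(net)
    for extra in [("a", "c"), ("e", "f"), ("b", "d")]:
        net2 = _net_from_edges(nodes, edges + [extra])
        rep2 = tn.topology_report(net2)
        assert rep2.edge_number == rep.edge_number + 1
        assert rep2.edge_density > rep.edge_density
        assert rep2.connectedness >= rep.connectedness
        d1 = dict(net.graph.degree)
        d2 = dict(net2.graph.degree)
        assert all(d2[v] >= d1[v] for v in nodes)
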