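"""Independent brute-force graph oracles shared by the network tests.

Shortest paths come from explicit simple-path enumeration, modularity from
exhaustive set-partition search; nothing here calls networkx algorithms.
"""

import itertools
import math

import networkx as nx

from twignet.network import TraitNetwork

def _all_simple_paths(adj, s, t):
    """Enumerate all simple s-t paths by depth-first search."""
    paths, stack = [], [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            paths.append(path)
            continue
        for w in sorted(adj[v]):
            if w not in path:
                stack.append((w, path + [w]))
    return paths

def _shortest_path_data(adj, nodes):
    """For each pair: geodesic length, count, and per-node pass-through count."""
    data = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            data[(s, t)] = None
            continue
        dmin = min(len(p) - 1 for p in paths)
        geos = [p for p in paths if len(p) - 1 == dmin]
        through = {v: sum(v in p[1:-1] for p in geos) for v in nodes}
        data[(s, t)] = (dmin, len(geos), through)
    return data

def _oracle_metrics(adj, nodes):
    n = len(nodes)
    sp = _shortest_path_data(adj, nodes)
    deg = {v: len(adj[v]) for v in nodes}
    m = sum(deg.values()) // 2
    bet = {v: 0.0 for v in nodes}
    reach, plsum = 0, 0
    for pair, d in sp.items():
        if d is None:
            continue
        reach += 1
        plsum += d[0]
        for v in nodes:
            bet[v] += d[2][v] / d[1]
    clust = {}
    for v in nodes:
        nb = sorted(adj[v])
        if len(nb) < 2:
            clust[v] = 0.0
        else:
            links = sum(b in adj[a] for a, b in itertools.combinations(nb, 2))
            clust[v] = links / (len(nb) * (len(nb) - 1) / 2)
    pairs = n * (n - 1) // 2
    dmax = max(deg.values())
    out = {
        "degree": deg,
        "betweenness": bet,
        "clustering": clust,
        "edge_number": m,
        "edge_density": m / pairs,
        "connectedness": reach / pairs,
        "average_degree": 2 * m / n,
        "average_path_length": plsum / reach if reach else float("nan"),
        "centralization": sum(dmax - d for d in deg.values()) / ((n - 1) * (n - 2)),
    }
    return out

def _oracle_modularity(adj, nodes, partition):
    m = sum(len(a) for a in adj.values()) / 2
    q = 0.0
    for comm in partition:
        e_in = sum(1 for a, b in itertools.combinations(sorted(comm), 2) if b in adj[a])
        d_sum = sum(len(adj[v]) for v in comm)
        q += e_in / m - (d_sum / (2 * m)) ** 2
    return q

def _oracle_best_partition(adj, nodes):
    best_q = -math.inf
    for part in _brute_partitions(list(nodes)):
        q = _oracle_modularity(adj, nodes, part)
        best_q = max(best_q, q)
    return best_q

def _brute_partitions(items):
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _brute_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {head}] + part[i + 1 :]
        yield part + [{head}]

def _net_from_edges(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return TraitNetwork(graph=g, subset="all")

def _adj(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


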