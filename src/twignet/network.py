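"""Plant trait networks (PTNs) from significance-filtered Spearman correlations.

Nodes are the 17 twig traits; an edge joins two traits whose tie-corrected
Spearman correlation over replicate plot means is significant (two-sided
p < α, unadjusted). Edges carry the correlation, its p-value, and its sign;
topology metrics (degree, betweenness, clustering, density, connectedness,
average path length, Freeman degree centralization, modularity) are computed
on the unweighted graph, matching the integer degrees reported for such
networks. Betweenness is reported both raw (sum over node pairs of the
fraction of shortest paths through a node) and normalized by (n−1)(n−2)/2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .traits import TRAIT_ORDER

__all__ = [
    "TraitNetwork",
    "TopologyReport",
    "spearman_matrix",
    "build_ptn",
    "node_centralities",
    "detect_communities",
    "topology_report",
    "key_traits",
    "subset_levels",
]

#: Data subsets used for per-treatment networks: the control plus every
#: level of that series (N20P4 participates in both combined series).
SUBSET_LEVELS: Mapping[str, tuple[str, ...]] = {
    "N": ("CK", "N10", "N20", "N40"),
    "P": ("CK", "P2", "P4", "P8"),
    "N20Px": ("CK", "N20P2", "N20P4", "N20P8"),
    "NxP4": ("CK", "N10P4", "N20P4", "N40P4"),
}


def subset_levels(subset: str) -> tuple[str, ...] | None:
    """Treatment levels entering a per-series PTN; None means all rows."""
    if subset == "all":
        return None
    try:
        return SUBSET_LEVELS[subset]
    except KeyError:
        raise KeyError(f"unknown subset {subset!r}; expected N, P, N20Px, NxP4 or all")


def spearman_matrix(
    plot_table: pd.DataFrame, traits: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tie-corrected Spearman rho and two-sided p over trait columns.

    Requires at least 4 rows. Constant columns produce NaN rho/p, which
    :func:`build_ptn` excludes from the edge set.
    """
    traits = [t for t in (traits or TRAIT_ORDER) if t in plot_table.columns]
    x = plot_table[list(traits)].to_numpy(float)
    if x.shape[0] < 4:
        raise ValueError("Spearman matrix requires at least 4 rows")
    constant = np.array([np.unique(col).size < 2 for col in x.T])
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.spearmanr(x)
    if np.ndim(res.statistic) == 0:  # scipy returns a scalar for 2 columns
        r, pv = float(res.statistic), float(res.pvalue)
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    else:
        rho = np.array(res.statistic, float)
        p = np.array(res.pvalue, float)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )


@dataclass
class TraitNetwork:
    """Significance-filtered signed correlation graph over traits."""

    graph: nx.Graph
    subset: str = "all"
    alpha: float = 0.05

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"trait_a": a, "trait_b": b, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "rho", "p", "sign"])


def build_ptn(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    alpha: float = 0.05,
    subset: str = "all",
    categories: Mapping[str, str] | None = None,
) -> TraitNetwork:
    """Retain every trait pair with p < alpha as an edge.

    All traits remain nodes even when isolated; pairs with undefined
    (NaN) correlations are never edges.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    names = list(rho.columns)
    g = nx.Graph()
    for name in names:
        g.add_node(name, category=(categories or {}).get(name, ""))
    for a, b in itertools.combinations(names, 2):
        pv = p.loc[a, b]
        r = rho.loc[a, b]
        if np.isfinite(pv) and np.isfinite(r) and pv < alpha:
            g.add_edge(a, b, rho=float(r), p=float(pv),
                       sign="positive" if r >= 0 else "negative", weight=abs(float(r)))
    return TraitNetwork(graph=g, subset=subset, alpha=alpha)


def node_centralities(network: TraitNetwork) -> pd.DataFrame:
    """Degree, raw and normalized betweenness, and local clustering per trait."""
    g = network.graph
    n = g.number_of_nodes()
    bet_raw = nx.betweenness_centrality(g, normalized=False)
    denom = (n - 1) * (n - 2) / 2.0 if n > 2 else np.nan
    clust = nx.clustering(g)
    rows = [
        {
            "trait": v,
            "degree": g.degree[v],
            "betweenness": bet_raw[v],
            "betweenness_norm": bet_raw[v] / denom if denom and np.isfinite(denom) else np.nan,
            "clustering": clust[v],
        }
        for v in sorted(g.nodes)
    ]
    return pd.DataFrame(rows)


def _partitions(items: list):
    """All set partitions of `items` in a deterministic refinement order."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _refine_partition(h: nx.Graph, partition: list[set[str]]) -> list[set[str]]:
    """Deterministic local refinement of a partition: single-node moves and
    pairwise community merges are applied while modularity strictly
    improves; nodes and communities are visited in sorted order."""

    def q_of(part: list[set[str]]) -> float:
        return nx.community.modularity(h, [c for c in part if c], weight=None)

    best_q = q_of(partition)
    improved = True
    while improved:
        improved = False
        for v in sorted(h.nodes):
            src = next(i for i, c in enumerate(partition) if v in c)
            for dst in range(len(partition) + 1):
                if dst == src:
                    continue
                trial = [set(c) for c in partition] + ([set()] if dst == len(partition) else [])
                trial[src].discard(v)
                trial[dst].add(v)
                q = q_of(trial)
                if q > best_q + 1e-12:
                    partition = [c for c in trial if c]
                    best_q = q
                    improved = True
                    break
        for i, j in itertools.combinations(range(len(partition)), 2):
            trial = [c for k, c in enumerate(partition) if k not in (i, j)]
            trial.append(partition[i] | partition[j])
            q = q_of(trial)
            if q > best_q + 1e-12:
                partition = trial
                best_q = q
                improved = True
                break
    return partition


def detect_communities(
    network: TraitNetwork, method: str = "auto"
) -> tuple[list[set[str]], float]:
    """Community partition maximizing modularity Q on the unweighted graph.

    ``method="greedy"`` uses deterministic greedy agglomeration followed by a
    deterministic local refinement (single-node moves and community merges);
    ``method="exact"`` enumerates all set partitions (allowed up to 12
    nodes) and returns the first optimum in enumeration order;
    ``method="auto"`` (default) runs the exact search on graphs of up to 8
    nodes, where it is instantaneous, and the greedy heuristic otherwise.
    Graphs without edges yield singleton communities and Q = NaN
    (modularity is undefined with no edges).
    """
    g = network.graph
    nodes = sorted(g.nodes)
    if g.number_of_edges() == 0:
        return [{v} for v in nodes], float("nan")
    h = nx.Graph()
    h.add_nodes_from(nodes)
    h.add_edges_from(sorted((min(a, b), max(a, b)) for a, b in g.edges))
    if method == "auto":
        method = "exact" if len(nodes) <= 8 else "greedy"
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(h, weight=None)
        partition = _refine_partition(h, [set(c) for c in comms])
    elif method == "exact":
        if len(nodes) > 12:
            raise ValueError("exact community search is limited to 12 nodes")
        best, best_q = None, -math.inf
        for part in _partitions(nodes):
            q = nx.community.modularity(h, [set(c) for c in part], weight=None)
            if q > best_q + 1e-12:
                best, best_q = part, q
        partition = [set(c) for c in best]
    else:
        raise ValueError(f"unknown method {method!r}")
    q = nx.community.modularity(h, partition, weight=None)
    partition.sort(key=lambda c: sorted(c))
    return partition, float(q)


@dataclass(frozen=True)
class TopologyReport:
    """Whole-network topology parameters of a PTN."""

    subset: str
    n_nodes: int
    edge_number: int
    edge_density: float
    connectedness: float
    average_degree: float
    average_path_length: float  # over reachable pairs; NaN when no edges
    average_clustering: float
    degree_centralization: float
    modularity: float  # NaN when no edges
    partition: tuple[tuple[str, ...], ...]
    degenerate: bool  # True when the graph has no edges

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "subset", "n_nodes", "edge_number", "edge_density", "connectedness",
            "average_degree", "average_path_length", "average_clustering",
            "degree_centralization", "modularity", "degenerate")}
        d["partition"] = [list(c) for c in self.partition]
        return d


def topology_report(network: TraitNetwork, community_method: str = "auto") -> TopologyReport:
    """Compute the whole-network topology parameters of a PTN."""
    g = network.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    pairs = n * (n - 1) // 2
    degrees = np.array([d for _, d in g.degree])

    reachable = 0
    path_sum = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) > 1:
            for _, dists in nx.all_pairs_shortest_path_length(sub):
                path_sum += sum(dists.values())
            reachable += len(comp) * (len(comp) - 1) // 2
    avg_path = (path_sum / 2) / reachable if reachable else float("nan")

    if n > 2:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = float("nan")
    partition, q = detect_communities(network, method=community_method)
    return TopologyReport(
        subset=network.subset,
        n_nodes=n,
        edge_number=m,
        edge_density=m / pairs if pairs else float("nan"),
        connectedness=reachable / pairs if pairs else float("nan"),
        average_degree=float(degrees.mean()) if n else float("nan"),
        average_path_length=float(avg_path),
        average_clustering=float(np.mean([c for c in nx.clustering(g).values()])) if n else float("nan"),
        degree_centralization=centralization,
        modularity=q,
        partition=tuple(tuple(sorted(c)) for c in partition),
        degenerate=(m == 0),
    )


def key_traits(centralities: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Rank traits by degree, then betweenness, then name; flag the key set.

    Returns (ranked trait list, key traits) where the key traits are all
    traits attaining the maximal (degree, betweenness) pair.
    """
    if centralities.empty:
        raise ValueError("empty centrality table")
    df = centralities.sort_values(
        ["degree", "betweenness", "trait"], ascending=[False, False, True]
    )
    top_deg = df["degree"].iloc[0]
    top_bet = df.loc[df["degree"] == top_deg, "betweenness"].max()
    key = df.loc[(df["degree"] == top_deg) & (df["betweenness"] == top_bet), "trait"].tolist()
    return df["trait"].tolist(), sorted(key)
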