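"""Graph-analytic reporting on an estimated comorbidity network: global
statistics, positive-edge filtering, degree rankings, strongest edges and
modularity partitioning."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import networkx as nx

from .containers import GraphSummary, ModularityPartition, WeightMatrix

__all__ = [
    "to_graph",
    "summarize",
    "positive_filter",
    "degree_tables",
    "top_edges",
    "modularity_partition",
]


def _require_symmetric(w: WeightMatrix) -> None:
    if not w.symmetric:
        raise ValueError("operation requires a symmetrized weight matrix")


def to_graph(w: WeightMatrix, drop_isolated: bool = True) -> nx.Graph:
    """networkx view of the nonzero edges, node names = category labels,
    edge attribute ``weight`` = logOR."""
    g = nx.Graph()
    g.add_nodes_from(w.categories)
    idx_i, idx_j = np.nonzero(np.triu(w.values, k=1))
    for i, j in zip(idx_i, idx_j):
        g.add_edge(w.categories[i], w.categories[j], weight=float(w.values[i, j]))
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def summarize(w: WeightMatrix) -> GraphSummary:
    """Global statistics of the unweighted graph of nonzero edges, restricted
    to non-isolated nodes.  Diameter and average distance use unweighted
    shortest paths over the largest connected component; average distance
    averages over all unordered pairs within it."""
    _require_symmetric(w)
    g = to_graph(w, drop_isolated=True)
    if g.number_of_nodes() == 0:
        warnings.warn("empty graph: all summary statistics are zero")
        return GraphSummary(0, 0, 0.0, 0.0, 0, 0.0, 0)
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    nv = g.number_of_nodes()
    ne = g.number_of_edges()
    if giant.number_of_nodes() > 1:
        diameter = nx.diameter(giant)
        avg_dist = nx.average_shortest_path_length(giant)
    else:
        diameter, avg_dist = 0, 0.0
    return GraphSummary(
        node_count=nv,
        edge_count=ne,
        edge_density=2.0 * ne / (nv * (nv - 1)) if nv > 1 else 0.0,
        global_transitivity=nx.transitivity(g),
        diameter=int(diameter),
        average_distance=float(avg_dist),
        component_count=len(components),
    )


def positive_filter(w: WeightMatrix, min_logor: float = 1.0) -> WeightMatrix:
    """Keep only clinically prominent positive associations: entries below
    ``min_logor`` (including all negative entries) are set to zero.  The
    threshold is inclusive ("not < 1" keeps exactly 1.0)."""
    _require_symmetric(w)
    vals = np.where(w.values >= min_logor, w.values, 0.0)
    np.fill_diagonal(vals, 0.0)
    return WeightMatrix(values=vals, categories=w.categories, symmetric=True, method=w.method)


def degree_tables(w: WeightMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked (descending) tables of unweighted degree (count of nonzero
    incident edges) and weighted degree (sum of incident absolute weights).
    Ties rank lexicographically by category label; isolated nodes are
    excluded from the listings."""
    _require_symmetric(w)
    adj = w.values
    unweighted = (adj != 0).sum(axis=0)
    weighted = np.abs(adj).sum(axis=0)
    frame = pd.DataFrame(
        {
            "category": w.categories,
            "unweighted_degree": unweighted.astype(int),
            "weighted_degree": weighted,
        }
    )
    frame = frame[frame["unweighted_degree"] > 0]
    by_unw = frame.sort_values(
        ["unweighted_degree", "category"], ascending=[False, True]
    ).reset_index(drop=True)[["category", "unweighted_degree"]]
    by_w = frame.sort_values(
        ["weighted_degree", "category"], ascending=[False, True]
    ).reset_index(drop=True)[["category", "weighted_degree"]]
    return by_unw, by_w


def top_edges(w: WeightMatrix, k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The k most-positive and k most-negative edges, one row per unordered
    pair, columns (category_i, category_j, weight).  If fewer such edges
    exist, all are returned."""
    _require_symmetric(w)
    idx_i, idx_j = np.nonzero(np.triu(w.values, k=1))
    edges = pd.DataFrame(
        {
            "category_i": [w.categories[i] for i in idx_i],
            "category_j": [w.categories[j] for j in idx_j],
            "weight": w.values[idx_i, idx_j],
        }
    )
    pos = (
        edges[edges["weight"] > 0]
        .sort_values(["weight", "category_i", "category_j"], ascending=[False, True, True])
        .head(k)
        .reset_index(drop=True)
    )
    neg = (
        edges[edges["weight"] < 0]
        .sort_values(["weight", "category_i", "category_j"], ascending=[True, True, True])
        .head(k)
        .reset_index(drop=True)
    )
    return pos, neg


def modularity_partition(
    w: WeightMatrix, resolution: float = 1.0, seed: int = 0
) -> ModularityPartition:
    """Louvain community detection on the weighted graph.

    Weights must be nonnegative (apply :func:`positive_filter` first when the
    matrix has negative entries).  Classes are relabeled contiguously from 0
    in decreasing size order; the partition is deterministic given the seed.
    """
    _require_symmetric(w)
    if np.any(w.values < 0):
        raise ValueError("modularity partitioning requires nonnegative weights")
    g = to_graph(w, drop_isolated=True)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda s: (-len(s), sorted(s)[0]))
    class_of = {node: ci for ci, comm in enumerate(communities) for node in comm}
    score = nx.community.modularity(g, communities, weight="weight", resolution=resolution)
    return ModularityPartition(
        class_of=class_of, class_count=len(communities), modularity_score=float(score)
    )
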