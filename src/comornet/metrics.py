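"""Distances between an estimated network and the generative truth.

Three complementary views: the Euclidean (Frobenius) distance compares the
labeled weight matrices entry by entry; the spectral distance compares the
sorted combinatorial-Laplacian spectra of the weighted graphs (a
permutation-invariant global comparison); NetSimile compares
35-dimensional feature signatures (7 local node features x 5 moment
aggregators) by Canberra distance, also permutation-invariant.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .containers import DistanceReport, WeightMatrix

__all__ = [
    "euclidean_distance",
    "spectral_distance",
    "netsimile",
    "netsimile_signature",
    "distance_report",
]


def _check_pair(w1: WeightMatrix, w2: WeightMatrix, check_labels: bool) -> None:
    if w1.p != w2.p:
        raise ValueError(f"dimension mismatch: {w1.p} vs {w2.p}")
    if check_labels and w1.categories != w2.categories:
        raise ValueError("category orderings differ")


def euclidean_distance(w1: WeightMatrix, w2: WeightMatrix) -> float:
    """Frobenius norm of the elementwise difference over the full symmetric
    matrix (both off-diagonal copies of each pair contribute)."""
    _check_pair(w1, w2, check_labels=True)
    return float(np.linalg.norm(w1.values - w2.values, ord="fro"))


def _binary_adjacency(w: WeightMatrix) -> np.ndarray:
    return (w.values != 0).astype(float)


def spectral_distance(w1: WeightMatrix, w2: WeightMatrix, binarize: bool = False) -> float:
    """l2 distance between the sorted combinatorial-Laplacian eigenvalue
    spectra of the two graphs.

    By default the Laplacian of the weighted graph (absolute weights) is
    used, so the distance reflects association strength as well as
    structure; ``binarize=True`` compares the unweighted (nonzero -> edge)
    topologies instead.  Spectra of unequal length would be zero-padded;
    equal dimensions are enforced upstream."""
    _check_pair(w1, w2, check_labels=False)
    spectra = []
    for w in (w1, w2):
        a = _binary_adjacency(w) if binarize else np.abs(w.values)
        lap = np.diag(a.sum(axis=1)) - a
        spectra.append(np.sort(np.linalg.eigvalsh(lap)))
    s1, s2 = spectra
    if s1.size != s2.size:  # defensive; cannot happen after _check_pair
        pad = max(s1.size, s2.size)
        s1 = np.pad(s1, (pad - s1.size, 0))
        s2 = np.pad(s2, (pad - s2.size, 0))
    return float(np.linalg.norm(s1 - s2))


def _node_features(g: nx.Graph) -> np.ndarray:
    """The 7 NetSimile per-node features: degree, clustering coefficient,
    mean neighbor degree, mean neighbor clustering, ego-net edge count,
    edges leaving the ego-net, and number of outside neighbors of the
    ego-net."""
    nodes = list(g.nodes)
    clus = nx.clustering(g)
    feats = np.zeros((len(nodes), 7))
    for row, u in enumerate(nodes):
        nbrs = set(g.neighbors(u))
        deg = len(nbrs)
        feats[row, 0] = deg
        feats[row, 1] = clus[u]
        if deg:
            feats[row, 2] = np.mean([g.degree(v) for v in nbrs])
            feats[row, 3] = np.mean([clus[v] for v in nbrs])
        ego = nbrs | {u}
        ego_edges = 0
        outgoing = 0
        outside: set = set()
        for v in ego:
            for t in g.neighbors(v):
                if t in ego:
                    ego_edges += 1
                else:
                    outgoing += 1
                    outside.add(t)
        feats[row, 4] = ego_edges // 2
        feats[row, 5] = outgoing
        feats[row, 6] = len(outside)
    return feats


def _aggregate(col: np.ndarray) -> np.ndarray:
    """Mean, median, standard deviation, skewness and (non-excess) kurtosis
    of one feature column; zero-variance columns get 0 skew and kurtosis."""
    mean = col.mean()
    med = float(np.median(col))
    var = float(np.mean((col - mean) ** 2))
    sd = np.sqrt(var)
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean((col - mean) ** 3) / sd**3)
        kurt = float(np.mean((col - mean) ** 4) / var**2)
    return np.array([mean, med, sd, skew, kurt])


def netsimile_signature(w: WeightMatrix) -> np.ndarray:
    """35-dimensional signature of the binarized graph: the 5 aggregators of
    each of the 7 node features, ordered feature-major."""
    g = nx.from_numpy_array(_binary_adjacency(w))
    if g.number_of_nodes() == 0:
        return np.zeros(35)
    feats = _node_features(g)
    return np.concatenate([_aggregate(feats[:, k]) for k in range(7)])


def _canberra(u: np.ndarray, v: np.ndarray) -> float:
    num = np.abs(u - v)
    den = np.abs(u) + np.abs(v)
    mask = den > 0  # terms with both components zero contribute 0
    return float(np.sum(num[mask] / den[mask]))


def netsimile(w1: WeightMatrix, w2: WeightMatrix) -> float:
    """Canberra distance between the NetSimile signatures of the two
    binarized graphs."""
    _check_pair(w1, w2, check_labels=False)
    return _canberra(netsimile_signature(w1), netsimile_signature(w2))


def distance_report(
    estimate: WeightMatrix, truth: WeightMatrix, method_label: str = ""
) -> DistanceReport:
    """All three distances of an estimate from the truth."""
    return DistanceReport(
        euclidean=euclidean_distance(estimate, truth),
        spectral=spectral_distance(estimate, truth),
        netsimile=netsimile(estimate, truth),
        method_label=method_label or estimate.method,
    )
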