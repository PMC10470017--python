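"""Network comparison metrics: Frobenius, Laplacian-spectral, NetSimile."""

import numpy as np
import networkx as nx
import pytest

from comornet import ising
from comornet.containers import WeightMatrix, as_weight_matrix
from comornet.metrics import (
    euclidean_distance,
    netsimile,
    netsimile_signature,
    spectral_distance,
)

from conftest import random_weight_matrix


def wm(values, cats=None):
    values = np.asarray(values, dtype=float)
    cats = cats or [f"D{i:03d}" for i in range(values.shape[0])]
    return WeightMatrix(values=values, categories=cats, symmetric=True)


def from_graph(g, n_nodes):
    a = np.zeros((n_nodes, n_nodes))
    for u, v in g.edges:
        a[u, v] = a[v, u] = 1.0
    return wm(a)


# ---------- independent NetSimile oracle (pure-python recomputation) ----------

def oracle_signature(adj):
    """NetSimile signature computed from scratch with adjacency sets."""
    import statistics

    n = adj.shape[0]
    nbrs = [set(np.flatnonzero(adj[i])) for i in range(n)]

    def clustering(i):
        k = len(nbrs[i])
        if k < 2:
            return 0.0
        links = sum(1 for u in nbrs[i] for v in nbrs[i] if u < v and v in nbrs[u])
        return 2.0 * links / (k * (k - 1))

    rows = []
    for i in range(n):
        deg = len(nbrs[i])
        ci = clustering(i)
        mean_nd = sum(len(nbrs[j]) for j in nbrs[i]) / deg if deg else 0.0
        mean_nc = sum(clustering(j) for j in nbrs[i]) / deg if deg else 0.0
        ego = nbrs[i] | {i}
        ego_edges = sum(1 for u in ego for v in ego if u < v and v in nbrs[u])
        outgoing = sum(1 for u in ego for v in nbrs[u] if v not in ego)
        outside = {v for u in ego for v in nbrs[u] if v not in ego}
        rows.append([deg, ci, mean_nd, mean_nc, ego_edges, outgoing, len(outside)])
    sig = []
    for k in range(7):
        col = [r[k] for r in rows]
        mean = statistics.fmean(col)
        med = statistics.median(col)
        var = statistics.fmean([(v - mean) ** 2 for v in col])
        sd = var**0.5
        if sd == 0:
            skew = kurt = 0.0
        else:
            skew = statistics.fmean([(v - mean) ** 3 for v in col]) / sd**3
            kurt = statistics.fmean([(v - mean) ** 4 for v in col]) / var**2
        sig.extend([mean, med, sd, skew, kurt])
    return np.array(sig)


def oracle_canberra(u, v):
    total = 0.0
    for a, b in zip(u, v):
        if abs(a) + abs(b) > 0:
            total += abs(a - b) / (abs(a) + abs(b))
    return total


# Canberra distance between the oracle signatures of the star K_{1,5} and the
# path P6, frozen from the brute-force computation above
STAR5_VS_PATH6 = 13.16452791641193


class TestEuclidean:
    def test_identity_and_symmetry(self):
        a = random_weight_matrix(8, seed=1)
        b = random_weight_matrix(8, seed=2)
        assert euclidean_distance(a, a) == 0.0
        assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_single_pair_difference(self):
        a = wm(np.zeros((4, 4)))
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 2.0
        assert euclidean_distance(a, wm(v)) == pytest.approx(np.sqrt(8.0), abs=1e-12)

    def test_compares_labeled_matrices(self):
        """Unlike the structural metrics, the Frobenius distance is not
        invariant under node permutation."""
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 1.0
        u = np.zeros((3, 3))
        u[1, 2] = u[2, 1] = 1.0
        assert euclidean_distance(wm(v), wm(u)) > 0
        assert spectral_distance(wm(v), wm(u)) == pytest.approx(0.0, abs=1e-9)
        assert netsimile(wm(v), wm(u)) == pytest.approx(0.0, abs=1e-12)

    def test_dimension_and_label_checks(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance(wm(np.zeros((3, 3))), wm(np.zeros((4, 4))))
        with pytest.raises(ValueError, match="orderings"):
            euclidean_distance(wm(np.zeros((2, 2)), ["A", "B"]), wm(np.zeros((2, 2)), ["B", "A"]))


class TestSpectral:
    def test_empty_vs_complete_k3(self):
        empty = wm(np.zeros((3, 3)))
        k3 = wm(1 - np.eye(3))
        assert spectral_distance(empty, k3) == pytest.approx(np.sqrt(18.0), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        a = random_weight_matrix(10, seed=3)
        perm = rng.permutation(10)
        b = wm(a.values[np.ix_(perm, perm)])
        assert spectral_distance(a, b) == pytest.approx(0.0, abs=1e-8)

    def test_weighted_default_vs_binarized_option(self):
        """The default spectrum is weight-sensitive; binarize=True compares
        topology only."""
        v1 = np.zeros((3, 3))
        v1[0, 1] = v1[1, 0] = 1.0
        v2 = np.zeros((3, 3))
        v2[0, 1] = v2[1, 0] = 2.0
        assert spectral_distance(wm(v1), wm(v2)) > 0
        assert spectral_distance(wm(v1), wm(v2), binarize=True) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_inequality_on_random_triples(self):
        for seed in range(5):
            a = random_weight_matrix(8, seed=3 * seed)
            b = random_weight_matrix(8, seed=3 * seed + 1)
            c = random_weight_matrix(8, seed=3 * seed + 2)
            dab = spectral_distance(a, b)
            dbc = spectral_distance(b, c)
            dac = spectral_distance(a, c)
            assert dac <= dab + dbc + 1e-9


class TestNetSimile:
    def test_relabeled_copy_distance_zero(self):
        rng = np.random.default_rng(9)
        a = random_weight_matrix(12, seed=5)
        perm = rng.permutation(12)
        b = wm(a.values[np.ix_(perm, perm)])
        assert netsimile(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self):
        a = random_weight_matrix(9, seed=6)
        b = random_weight_matrix(9, seed=7)
        assert netsimile(a, b) == pytest.approx(netsimile(b, a), abs=1e-12)

    def test_star_vs_path_matches_oracle(self):
        star = from_graph(nx.star_graph(5), 6)
        path = from_graph(nx.path_graph(6), 6)
        sig_star = oracle_signature((star.values != 0).astype(float))
        sig_path = oracle_signature((path.values != 0).astype(float))
        assert np.allclose(netsimile_signature(star), sig_star, atol=1e-12)
        assert np.allclose(netsimile_signature(path), sig_path, atol=1e-12)
        expected = oracle_canberra(sig_star, sig_path)
        got = netsimile(star, path)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(STAR5_VS_PATH6, abs=1e-9)
        assert got > 0

    def test_ensemble_separation(self):
        """Signatures of same-sparsity random networks are closer on average
        than signatures across different sparsities."""
        same, cross = [], []
        for seed in range(10):
            a = as_weight_matrix(ising.random_network(20, 0.1, seed=100 + seed))
            b = as_weight_matrix(ising.random_network(20, 0.1, seed=200 + seed))
            c = as_weight_matrix(ising.random_network(20, 0.4, seed=300 + seed))
            same.append(netsimile(a, b))
            cross.append(netsimile(a, c))
        assert np.mean(same) < np.mean(cross)


class TestCommonProperties:
    @pytest.mark.parametrize("metric", [euclidean_distance, spectral_distance, netsimile])
    def test_nonnegative_zero_self(self, metric):
        a = random_weight_matrix(7, seed=8)
        b = random_weight_matrix(7, seed=9)
        assert metric(a, a) == pytest.approx(0.0, abs=1e-9)
        assert metric(a, b) >= 0
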