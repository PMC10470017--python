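import numpy as np
import pytest

from comornet import ising
from comornet.containers import IsingNetwork, WeightMatrix, as_weight_matrix


@pytest.fixture(scope="session")
def chain3_network():
    """3-node chain A-B-C: W_AB = W_BC = 1, W_AC = 0 (B confounds A and C)."""
    w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    tau = -np.clip(w, 0, None).sum(axis=1) / 2
    return IsingNetwork(weights=w, thresholds=tau)


@pytest.fixture(scope="session")
def small_net():
    return ising.random_network(8, 0.3, seed=11)


@pytest.fixture(scope="session")
def small_data(small_net):
    return ising.sample(small_net, 1500, n_sweeps=50, seed=12)


def random_weight_matrix(p, seed, symmetric=True, density=0.3):
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    mask = rng.random(iu[0].size) < density
    vals = rng.normal(size=iu[0].size) * mask
    w[iu] = vals
    w = w + w.T
    return WeightMatrix(values=w, categories=[f"D{i:03d}" for i in range(p)], symmetric=True)


def edge_support(w: WeightMatrix) -> np.ndarray:
    iu = np.triu_indices(w.p, k=1)
    return (w.values[iu] != 0).astype(int)


def support_f1(estimate: WeightMatrix, truth: WeightMatrix) -> float:
    est, tru = edge_support(estimate), edge_support(truth)
    tp = int(np.sum((est == 1) & (tru == 1)))
    fp = int(np.sum((est == 1) & (tru == 0)))
    fn = int(np.sum((est == 0) & (tru == 1)))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)
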