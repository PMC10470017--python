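"""Ising-model ground truth and Metropolis-Hastings sampling of binary data.

This module plays two roles: it generates the random ground-truth networks
used to validate the estimators, and it is the package's synthetic-data
generator (every test fixture is drawn from it).

The model is the {0,1}-domain Ising model

    P(x) proportional to exp( sum_i tau_i x_i + sum_{i<j} W_ij x_i x_j )

whose conditional distributions are exactly logistic regressions of each
node on the others -- which is why nodewise penalized logistic regression
can recover W.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .containers import IsingNetwork, MorbidityMatrix

__all__ = ["random_network", "exact_distribution", "sample", "state_table"]

_ENUM_LIMIT = 15


def random_network(
    p: int,
    sparse_rate: float,
    seed: int,
    weight_low: float = 0.5,
    weight_high: float = 1.5,
    positive_prob: float = 0.9,
) -> IsingNetwork:
    """Draw a random Ising network with independent Bernoulli(sparse_rate)
    edges on the upper triangle.

    Nonzero weight magnitudes are Uniform(weight_low, weight_high) and the
    sign is positive with probability ``positive_prob`` (comorbidity
    networks are predominantly positive, with a minority of structural
    exclusions).  Thresholds are set to tau_i = -(sum_j max(W_ij, 0)) / 2,
    which centres node prevalences near one half and avoids degenerate
    all-zero or all-one columns.

    Parameters
    ----------
    p : number of nodes (>= 2)
    sparse_rate : probability that any given edge exists, in [0, 1]
    seed : RNG seed; the same seed reproduces the same network
    """
    if p < 2:
        raise ValueError(f"node count must be >= 2, got {p}")
    if not 0.0 <= sparse_rate <= 1.0:
        raise ValueError(f"sparse_rate must be in [0, 1], got {sparse_rate}")
    if weight_low < 0 or weight_high < weight_low:
        raise ValueError("need 0 <= weight_low <= weight_high")
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    n_pairs = iu[0].size
    present = rng.random(n_pairs) < sparse_rate
    mags = rng.uniform(weight_low, weight_high, size=n_pairs)
    signs = np.where(rng.random(n_pairs) < positive_prob, 1.0, -1.0)
    vals = np.where(present, mags * signs, 0.0)
    w[iu] = vals
    w = w + w.T
    tau = -np.clip(w, 0.0, None).sum(axis=1) / 2.0
    return IsingNetwork(weights=w, thresholds=tau, sparse_rate=sparse_rate)


def state_table(p: int) -> np.ndarray:
    """All 2^p binary states as a (2^p, p) array; state k has bit j of k in
    column j (node j is the j-th least significant bit)."""
    k = np.arange(2**p, dtype=np.int64)
    return ((k[:, None] >> np.arange(p)) & 1).astype(float)


def exact_distribution(network: IsingNetwork) -> np.ndarray:
    """Exact state probabilities by full enumeration (oracle for the sampler).

    Returns a length-2^P vector indexed by the integer encoding of
    :func:`state_table`.  Refuses P > 15.
    """
    p = network.p
    if p > _ENUM_LIMIT:
        raise ValueError(f"exact enumeration limited to P <= {_ENUM_LIMIT}, got {p}")
    s = state_table(p)
    energy = s @ network.thresholds + 0.5 * np.einsum("ki,ij,kj->k", s, network.weights, s)
    energy -= energy.max()  # overflow guard
    prob = np.exp(energy)
    prob /= prob.sum()
    return prob


@njit(cache=True)
def _mh_kernel(w, tau, n, n_sweeps, seeds):  # pragma: no cover - jitted
    p = w.shape[0]
    out = np.empty((n, p), dtype=np.int8)
    for r in range(n):
        np.random.seed(seeds[r])
        x = np.empty(p, dtype=np.int8)
        for j in range(p):
            x[j] = 1 if np.random.random() < 0.5 else 0
        # local field f[i] = tau_i + sum_j W_ij x_j, kept incrementally
        f = tau.copy()
        for i in range(p):
            for j in range(p):
                if x[j] == 1:
                    f[i] += w[i, j]
        for _ in range(n_sweeps):
            for i in range(p):
                # flipping x_i changes the log-probability by +-f[i]
                delta = f[i] if x[i] == 0 else -f[i]
                if delta >= 0.0 or np.random.random() < np.exp(delta):
                    s = 1.0 if x[i] == 0 else -1.0
                    x[i] = 1 - x[i]
                    for j in range(p):
                        f[j] += s * w[j, i]
        out[r] = x
    return out


def sample(
    network: IsingNetwork,
    n: int,
    n_sweeps: int = 100,
    seed: int = 0,
    category_prefix: str = "D",
) -> MorbidityMatrix:
    """Draw ``n`` independent binary vectors from the Ising model by
    single-site Metropolis-Hastings.

    Each row is its own chain: a uniformly random initial state followed by
    ``n_sweeps`` full sweeps (one flip proposal per site per sweep, sites
    visited in order, acceptance min(1, exp(delta))), with the final state
    emitted.  Per-row RNG streams are derived deterministically from
    ``seed`` so output is bit-identical across runs.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    ss = np.random.SeedSequence(seed)
    row_seeds = ss.generate_state(n).astype(np.int64)  # uint32 values, fit int64
    values = _mh_kernel(
        np.ascontiguousarray(network.weights, dtype=np.float64),
        np.ascontiguousarray(network.thresholds, dtype=np.float64),
        int(n),
        int(n_sweeps),
        row_seeds,
    )
    cats = [f"{category_prefix}{i:03d}" for i in range(network.p)]
    rows = [f"S{i:05d}" for i in range(n)]
    return MorbidityMatrix(values=values, categories=cats, row_ids=rows)
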