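"""Core in-memory containers shared across the package.

The binary patient-by-category matrix, the generative Ising network, and the
estimated association (log odds ratio) matrix are plain dataclasses wrapping
numpy arrays plus label metadata.  They validate their own structural
invariants on construction so downstream code can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MorbidityMatrix",
    "IsingNetwork",
    "WeightMatrix",
    "GraphSummary",
    "ModularityPartition",
    "DistanceReport",
]


@dataclass
class MorbidityMatrix:
    """N x P binary indicator matrix: rows are patients, columns diagnosis
    categories (consolidated ICD-9 prefixes for real data, synthetic labels
    for simulated data)."""

    values: np.ndarray
    categories: list[str]
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("morbidity matrix must be 2-dimensional")
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("morbidity matrix must be binary (0/1)")
        self.values = self.values.astype(np.int8, copy=False)
        self.categories = [str(c) for c in self.categories]
        self.row_ids = [str(r) for r in self.row_ids]
        n, p = self.values.shape
        if len(self.categories) != p:
            raise ValueError(f"{len(self.categories)} labels for {p} columns")
        if len(self.row_ids) != n:
            raise ValueError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(set(self.categories)) != p:
            raise ValueError("duplicate category labels")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.categories)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MorbidityMatrix":
        return cls(
            values=frame.to_numpy(),
            categories=list(map(str, frame.columns)),
            row_ids=list(map(str, frame.index)),
        )


@dataclass
class IsingNetwork:
    """Ground-truth generative model over binary vectors x in {0,1}^P:

        P(x) proportional to exp( sum_i tau_i x_i + sum_{i<j} W_ij x_i x_j )

    ``weights`` is the symmetric zero-diagonal interaction matrix W and
    ``thresholds`` the per-node main effects tau."""

    weights: np.ndarray
    thresholds: np.ndarray
    sparse_rate: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if self.thresholds.shape != (w.shape[0],):
            raise ValueError("thresholds length must match node count")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))


@dataclass
class WeightMatrix:
    """P x P matrix of pairwise association strengths (log odds ratios).

    A zero entry means "no edge".  ``symmetric`` records whether the matrix
    has been symmetrized (estimators that regress each node on the others
    produce an asymmetric matrix first)."""

    values: np.ndarray
    categories: list[str]
    symmetric: bool = False
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        w = self.values
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        self.categories = [str(c) for c in self.categories]
        if len(self.categories) != w.shape[0]:
            raise ValueError("category labels must match matrix dimension")
        if self.symmetric and not np.array_equal(w, w.T):
            raise ValueError("matrix flagged symmetric but is not")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def edge_count(self) -> int:
        """Number of nonzero unordered pairs (only meaningful once symmetric)."""
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.values[iu]))


@dataclass
class GraphSummary:
    """Global statistics of the unweighted graph of nonzero edges."""

    node_count: int
    edge_count: int
    edge_density: float
    global_transitivity: float
    diameter: int
    average_distance: float
    component_count: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ModularityPartition:
    class_of: dict[str, int]
    class_count: int
    modularity_score: float


@dataclass
class DistanceReport:
    """Distances of one estimated network from the generative truth."""

    euclidean: float
    spectral: float
    netsimile: float
    method_label: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def as_weight_matrix(network: IsingNetwork, categories: list[str] | None = None) -> WeightMatrix:
    """View an Ising network's interaction matrix as a WeightMatrix for
    distance computations against estimates."""
    if categories is None:
        categories = [f"D{i:03d}" for i in range(network.p)]
    return WeightMatrix(
        values=network.weights.copy(), categories=categories, symmetric=True, method="truth"
    )
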