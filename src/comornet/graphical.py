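"""Nodewise elastic-net Ising graphical model estimation.

The estimator regresses each diagnosis category on all the others with an
elastic-net penalized logistic regression, selects the penalty strength per
node by the extended BIC, writes the selected coefficients (log odds
ratios) into the corresponding row of a P x P matrix, and finally
symmetrizes by the minimum-absolute-value (AND) rule: an association
survives only if both of its two nodewise regressions retain it, and the
more conservative of the two estimates is kept.

Because the conditional distributions of a binary Markov random field are
exactly these logistic regressions, the symmetrized matrix estimates the
interaction matrix of the underlying Ising model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._solver import enet_logistic_path, lambda_max
from .containers import MorbidityMatrix, WeightMatrix

__all__ = [
    "ElasticNetConfig",
    "NodewiseFit",
    "ebic",
    "fit_node",
    "fit_network",
    "symmetrize_min_abs",
]

logger = logging.getLogger(__name__)


@dataclass
class ElasticNetConfig:
    """Settings for the nodewise elastic-net fits.

    alpha
        Mixing proportion: fraction of LASSO in the penalty
        alpha*sum|b| + (1-alpha)/2*sum b^2.  The "percentage of LASSO"
        settings 100/90/70% correspond to alpha = 1.0/0.9/0.7; default 0.9.
    gamma_ebic
        Extended-BIC hyperparameter (0 recovers ordinary BIC); default 0.25,
        the eLasso convention for Ising model selection.
    n_lambda, lambda_min_ratio
        The penalty path: n_lambda log-spaced values from lambda_max (the
        smallest penalty giving an all-zero fit) down to
        lambda_min_ratio * lambda_max.
    lambda_path
        Explicit strictly-decreasing path overriding the rule above.
    """

    alpha: float = 0.9
    gamma_ebic: float = 0.25
    n_lambda: int = 100
    lambda_min_ratio: float = 0.001
    lambda_path: np.ndarray | None = None
    tol: float = 1e-7
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma_ebic < 0:
            raise ValueError("gamma_ebic must be >= 0")
        if self.lambda_path is not None:
            lp = np.asarray(self.lambda_path, dtype=float)
            if lp.ndim != 1 or lp.size == 0 or np.any(lp <= 0):
                raise ValueError("lambda_path must be positive")
            if lp.size > 1 and np.any(np.diff(lp) >= 0):
                raise ValueError("lambda_path must be strictly decreasing")
            self.lambda_path = lp

    def build_path(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.lambda_path is not None:
            return self.lambda_path
        lmax = lambda_max(X, y, self.alpha)
        return np.geomspace(lmax, self.lambda_min_ratio * lmax, self.n_lambda)


@dataclass
class NodewiseFit:
    """Result of one penalized logistic regression along the lambda path."""

    outcome_index: int
    intercept: float
    coefficients: np.ndarray  # length P-1, covariates in column order minus outcome
    selected_lambda: float
    ebic_value: float


def ebic(loglik: float, k: int, n: int, p_cov: int, gamma: float) -> float:
    """Extended Bayesian information criterion (Chen & Chen):

        -2*loglik + k*ln(n) + 2*gamma*k*ln(p_cov)

    where k is the number of nonzero coefficients, n the sample size and
    p_cov the number of candidate covariates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= p_cov:
        raise ValueError("need 0 <= k <= p_cov")
    return -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(p_cov)


def fit_node(
    data: MorbidityMatrix, outcome_index: int, config: ElasticNetConfig | None = None
) -> NodewiseFit:
    """Fit one node's elastic-net logistic regression and select lambda by
    minimum eBIC over the path (ties resolved toward the larger, sparser
    penalty).  Coefficients below the numerical zero tolerance are exactly 0.
    """
    config = config or ElasticNetConfig()
    if not 0 <= outcome_index < data.p:
        raise IndexError(f"outcome index {outcome_index} out of range")
    X = data.values.astype(np.float64)
    y = X[:, outcome_index].copy()
    if y.min() == y.max():
        raise ValueError(
            f"outcome column {data.categories[outcome_index]!r} is constant"
        )
    Xc = np.ascontiguousarray(np.delete(X, outcome_index, axis=1))
    path = config.build_path(Xc, y)
    coefs, intercepts, logliks = enet_logistic_path(
        Xc, y, config.alpha, path, tol=config.tol, zero_tol=config.zero_tol
    )
    n, p_cov = Xc.shape
    ks = np.count_nonzero(coefs, axis=1)
    crit = np.array(
        [ebic(logliks[i], int(ks[i]), n, p_cov, config.gamma_ebic) for i in range(len(path))]
    )
    best = int(np.argmin(crit))  # first minimum = largest lambda on ties
    return NodewiseFit(
        outcome_index=outcome_index,
        intercept=float(intercepts[best]),
        coefficients=coefs[best].copy(),
        selected_lambda=float(path[best]),
        ebic_value=float(crit[best]),
    )


def fit_network(
    data: MorbidityMatrix, config: ElasticNetConfig | None = None
) -> WeightMatrix:
    """Run the nodewise regressions over every category and assemble the
    (asymmetric) P x P log-odds-ratio matrix: row i holds the coefficients
    of the regression with outcome i."""
    config = config or ElasticNetConfig()
    p = data.p
    w = np.zeros((p, p))
    for i in range(p):
        try:
            fit = fit_node(data, i, config)
        except ValueError as exc:
            raise ValueError(f"nodewise fit failed for {data.categories[i]!r}: {exc}") from exc
        others = [j for j in range(p) if j != i]
        w[i, others] = fit.coefficients
    return WeightMatrix(
        values=w,
        categories=data.categories,
        symmetric=False,
        method=f"graphical(alpha={config.alpha})",
    )


def symmetrize_min_abs(asym: WeightMatrix) -> WeightMatrix:
    """AND-rule symmetrization: each pair (w_ij, w_ji) is replaced by the
    member with the smaller absolute value, so a pair with either entry
    zero becomes a non-edge.  On an exact magnitude tie with conflicting
    signs the row-major entry (i < j) wins; such ties are logged."""
    if asym.symmetric:
        raise ValueError("matrix is already symmetric")
    a = asym.values
    at = a.T
    out = np.where(np.abs(a) <= np.abs(at), a, at)
    # enforce row-major tie-break explicitly in the lower triangle
    out = np.triu(out) + np.triu(out, k=1).T
    ties = (np.abs(a) == np.abs(at)) & (a != at) & (a != 0)
    n_ties = int(np.count_nonzero(np.triu(ties, k=1)))
    if n_ties:
        logger.info("min-abs symmetrization: %d sign-conflict magnitude ties", n_ties)
    return WeightMatrix(
        values=out, categories=asym.categories, symmetric=True, method=asym.method
    )
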