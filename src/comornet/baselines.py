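"""Pairwise comparison estimators: marginal odds-ratio networks with
Fisher exact screening, and mutual-information networks with permutation
inference.

Both methods look at one pair of diagnosis categories at a time and do not
adjust for the remaining categories, which is exactly why they admit the
confounded, indirect associations the nodewise graphical estimator is
designed to exclude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import MorbidityMatrix, WeightMatrix

__all__ = [
    "ContingencyTable2x2",
    "contingency_table",
    "log_odds_ratio",
    "fit_pairwise_or",
    "binary_mutual_information",
    "fit_mutual_information",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one pair: a = both present, b = i only, c = j only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def contingency_table(x: np.ndarray, y: np.ndarray) -> ContingencyTable2x2:
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    return ContingencyTable2x2(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(~x & ~y)),
    )


def log_odds_ratio(table: ContingencyTable2x2, zero_cell: str = "haldane") -> float:
    """ln(ad / bc) with the Haldane-Anscombe +0.5 correction applied to all
    four cells whenever any cell is zero (``zero_cell="haldane"``), or NaN
    for such tables (``zero_cell="drop"``)."""
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0:
        if zero_cell == "drop":
            return float("nan")
        if zero_cell != "haldane":
            raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log(a * d / (b * c)))


def fit_pairwise_or(
    data: MorbidityMatrix, level: float = 0.05, zero_cell: str = "haldane"
) -> WeightMatrix:
    """Marginal log-odds-ratio network.

    For every unordered pair of categories a 2x2 contingency table is built;
    the weight is the log odds ratio and the two-sided Fisher exact p-value
    is Bonferroni-corrected over the number of actually tested pairs.
    Weights whose adjusted p-value is >= ``level`` are set to zero.
    Zero-variance columns are skipped with a warning and their pairs do not
    count toward the correction.
    """
    if data.p < 2:
        raise ValueError("need at least two categories")
    X = data.values.astype(bool)
    p = data.p
    variable = [i for i in range(p) if 0 < X[:, i].sum() < data.n]
    skipped = sorted(set(range(p)) - set(variable))
    if skipped:
        warnings.warn(
            f"skipping zero-variance categories: {[data.categories[i] for i in skipped]}"
        )
    pairs = [(i, j) for ii, i in enumerate(variable) for j in variable[ii + 1:]]
    m = len(pairs)
    w = np.zeros((p, p))
    for i, j in pairs:
        tab = contingency_table(X[:, i], X[:, j])
        lor = log_odds_ratio(tab, zero_cell=zero_cell)
        if np.isnan(lor):
            continue
        _, pval = stats.fisher_exact(tab.as_array(), alternative="two-sided")
        p_adj = min(1.0, pval * m)
        if p_adj < level:
            w[i, j] = w[j, i] = lor
    return WeightMatrix(values=w, categories=data.categories, symmetric=True, method="pairwise_or")


def binary_mutual_information(table: ContingencyTable2x2) -> float:
    """Plug-in (maximum-likelihood) mutual information of two binary
    variables, in nats."""
    counts = np.array([table.a, table.b, table.c, table.d], dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty table")
    pxy = counts / n
    px1 = pxy[0] + pxy[1]  # P(x=1)
    py1 = pxy[0] + pxy[2]  # P(y=1)
    marg = np.array([px1 * py1, px1 * (1 - py1), (1 - px1) * py1, (1 - px1) * (1 - py1)])
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / marg[mask])))


def _mi_from_counts(a: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """Vectorized MI for tables with fixed margins (r1 = x-ones, c1 = y-ones)
    as a function of the both-present count ``a``."""
    a = np.asarray(a, dtype=float)
    cells = np.stack([a, r1 - a, c1 - a, n - r1 - c1 + a]) / n
    marg = np.array(
        [r1 * c1, r1 * (n - c1), (n - r1) * c1, (n - r1) * (n - c1)], dtype=float
    ) / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = cells * np.log(cells / marg[:, None])
    terms[~np.isfinite(terms)] = 0.0  # 0 * log 0 = 0
    return terms.sum(axis=0)


def fit_mutual_information(
    data: MorbidityMatrix,
    n_perm: int = 999,
    level: float = 0.05,
    seed: int = 0,
) -> WeightMatrix:
    """Pairwise mutual-information network with permutation inference.

    The weight is the plug-in MI (nats) of the two binary columns.  The
    permutation p-value is (1 + #{MI_perm >= MI_obs}) / (n_perm + 1) under
    uniform shuffling of one column.  For binary columns with fixed margins
    a uniform shuffle makes the both-present count exactly hypergeometric,
    so permutation draws are sampled as hypergeometric counts rather than by
    materializing shuffled columns; the test is identical in distribution.
    p-values are Bonferroni-corrected over the tested pairs and
    non-significant weights set to zero.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if data.p < 2:
        raise ValueError("need at least two categories")
    rng = np.random.default_rng(seed)
    X = data.values.astype(bool)
    p, n = data.p, data.n
    variable = [i for i in range(p) if 0 < X[:, i].sum() < n]
    pairs = [(i, j) for ii, i in enumerate(variable) for j in variable[ii + 1:]]
    m = len(pairs)
    w = np.zeros((p, p))
    for i, j in pairs:
        tab = contingency_table(X[:, i], X[:, j])
        mi_obs = binary_mutual_information(tab)
        # canonical margins (min of ones/zeros) make the sampled MI null
        # distribution, hence the p-value, exactly invariant to relabeling
        # 0<->1 of either column under a fixed seed
        r1 = min(tab.a + tab.b, tab.c + tab.d)
        c1 = min(tab.a + tab.c, tab.b + tab.d)
        a_perm = rng.hypergeometric(c1, n - c1, r1, size=n_perm)
        mi_perm = _mi_from_counts(a_perm, r1, c1, n)
        pval = (1.0 + np.sum(mi_perm >= mi_obs - 1e-15)) / (n_perm + 1.0)
        if min(1.0, pval * m) < level:
            w[i, j] = w[j, i] = mi_obs
    return WeightMatrix(
        values=w, categories=data.categories, symmetric=True, method="mutual_information"
    )
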