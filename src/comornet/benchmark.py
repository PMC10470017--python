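"""Simulation benchmark: generate a random Ising network, sample binary
data, run every estimator, and measure how far each estimated weight
matrix is from the generative truth.

The canonical study design is six scenarios -- 100 nodes at sample sizes
5,000 and 10,000, each at sparse rates 0.05, 0.1 and 0.2 -- comparing the
pairwise odds-ratio network with the nodewise elastic-net graphical model
at 100/90/70% LASSO.  A scaled-down preset (50 nodes, smaller samples) is
provided for routine runs; a small-network preset (20 nodes) adds the
mutual-information baseline, which is too expensive at full size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, graphical, ising, metrics
from .containers import MorbidityMatrix, WeightMatrix, as_weight_matrix

__all__ = [
    "EstimatorSetting",
    "ScenarioSpec",
    "run_scenario",
    "run_suite",
    "six_scenarios",
    "DEFAULT_ESTIMATORS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstimatorSetting:
    """One estimator to run: method in {"graphical", "pairwise",
    "mutual_information"}; alpha applies to the graphical method only."""

    method: str
    alpha: float | None = None

    def label(self) -> str:
        if self.method == "graphical":
            return f"elastic_net_{int(round((self.alpha or 0) * 100))}"
        return self.method

    def estimate(self, data: MorbidityMatrix, seed: int = 0) -> WeightMatrix:
        if self.method == "graphical":
            cfg = graphical.ElasticNetConfig(alpha=self.alpha if self.alpha is not None else 0.9)
            return graphical.symmetrize_min_abs(graphical.fit_network(data, cfg))
        if self.method == "pairwise":
            return baselines.fit_pairwise_or(data)
        if self.method == "mutual_information":
            return baselines.fit_mutual_information(data, seed=seed)
        raise ValueError(f"unknown method {self.method!r}")


DEFAULT_ESTIMATORS = (
    EstimatorSetting("pairwise"),
    EstimatorSetting("graphical", 1.0),
    EstimatorSetting("graphical", 0.9),
    EstimatorSetting("graphical", 0.7),
)


@dataclass
class ScenarioSpec:
    """One simulation condition."""

    p: int
    n: int
    sparse_rate: float
    estimators: tuple[EstimatorSetting, ...] = DEFAULT_ESTIMATORS
    replicates: int = 5
    master_seed: int = 0
    n_sweeps: int = 100

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.estimators:
            raise ValueError("at least one estimator is required")


def _replicate_seeds(master_seed: int, replicates: int) -> np.ndarray:
    # keep derived seeds in int32 range
    return np.random.SeedSequence(master_seed).generate_state(replicates) % (2**31)


def run_scenario(spec: ScenarioSpec) -> pd.DataFrame:
    """Run every estimator on every replicate of one scenario.

    Each replicate draws a fresh network and dataset from a seed derived
    deterministically from the master seed.  Estimator failures are
    recorded as failed rows (NaN distances) and the run continues.
    Columns: sparsity, n, p, method, replicate, seed, euclidean, spectral,
    netsimile, failed, error.
    """
    rows = []
    seeds = _replicate_seeds(spec.master_seed, spec.replicates)
    for rep, seed in enumerate(seeds):
        seed = int(seed)
        net = ising.random_network(spec.p, spec.sparse_rate, seed=seed)
        data = ising.sample(net, spec.n, n_sweeps=spec.n_sweeps, seed=seed + 1)
        truth = as_weight_matrix(net, categories=data.categories)
        for est in spec.estimators:
            base = {
                "sparsity": spec.sparse_rate,
                "n": spec.n,
                "p": spec.p,
                "method": est.label(),
                "replicate": rep,
                "seed": seed,
            }
            try:
                w = est.estimate(data, seed=seed + 2)
                rep_result = metrics.distance_report(w, truth, method_label=est.label())
                rows.append(
                    base
                    | {
                        "euclidean": rep_result.euclidean,
                        "spectral": rep_result.spectral,
                        "netsimile": rep_result.netsimile,
                        "failed": False,
                        "error": "",
                    }
                )
            except Exception as exc:  # noqa: BLE001 - record and continue
                logger.warning("estimator %s failed on replicate %d: %s", est.label(), rep, exc)
                rows.append(
                    base
                    | {
                        "euclidean": np.nan,
                        "spectral": np.nan,
                        "netsimile": np.nan,
                        "failed": True,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def run_suite(specs: list[ScenarioSpec]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run several scenarios; returns (long results table, aggregate table).

    The aggregate takes the median over replicates of each distance within
    each (sparsity, n, method) cell -- the shape of the published comparison
    tables."""
    if not specs:
        raise ValueError("no scenarios given")
    long = pd.concat([run_scenario(s) for s in specs], ignore_index=True)
    agg = (
        long[~long["failed"]]
        .groupby(["sparsity", "n", "method"], sort=True)[["euclidean", "spectral", "netsimile"]]
        .median()
        .reset_index()
    )
    return long, agg


def six_scenarios(
    scale: str = "ci",
    master_seed: int = 0,
    estimators: tuple[EstimatorSetting, ...] = DEFAULT_ESTIMATORS,
    replicates: int = 5,
) -> list[ScenarioSpec]:
    """The six-scenario grid (three sparse rates x two sample sizes).

    ``scale="paper"`` uses 100 nodes with n in {5000, 10000};
    ``scale="ci"`` is a cheaper 50-node grid with n in {1000, 2000}.
    """
    if scale == "paper":
        p, ns = 100, (5000, 10000)
    elif scale == "ci":
        p, ns = 50, (1000, 2000)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    specs = []
    for rate in (0.05, 0.1, 0.2):
        for k, n in enumerate(ns):
            specs.append(
                ScenarioSpec(
                    p=p,
                    n=n,
                    sparse_rate=rate,
                    estimators=estimators,
                    replicates=replicates,
                    master_seed=master_seed + int(rate * 1000) * 10 + k,
                )
            )
    return specs
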