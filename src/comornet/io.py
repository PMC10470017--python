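"""File formats and the end-to-end pipeline.

Canonical interchange formats are plain text: long-format encounters CSV in,
edge-list CSV (sparse) as the primary weight-matrix output with an optional
full-matrix CSV, GraphML for Gephi-compatible visualization, and JSON for
reports and the run manifest.  Scenario configurations are TOML.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from . import __version__, analysis, baselines, graphical, morbidity
from .benchmark import EstimatorSetting, ScenarioSpec
from .containers import IsingNetwork, MorbidityMatrix, WeightMatrix

__all__ = [
    "PipelineConfig",
    "read_encounters_csv",
    "write_morbidity_csv",
    "read_morbidity_csv",
    "write_edge_list_csv",
    "read_edge_list_csv",
    "write_matrix_csv",
    "write_graphml",
    "write_network_csv",
    "read_network_csv",
    "read_scenario_toml",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; the defaults are the package's standard
    analysis choices (rare-category cutoff 20, 90% LASSO elastic net,
    positive-association threshold logOR >= 1)."""

    min_count: int = 20
    alpha: float = 0.9
    gamma_ebic: float = 0.25
    positive_threshold: float = 1.0
    method: str = "graphical"
    seed: int = 0
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.method not in {"graphical", "pairwise", "mutual_information"}:
            raise ValueError(f"unknown method {self.method!r}")


def read_encounters_csv(path: str | Path) -> list[morbidity.EncounterRecord]:
    """Load a long-format diagnosis table (patient_id, encounter_id,
    admit_time, icd9_code).  Schema violations are reported with the
    offending line number where identifiable."""
    frame = pd.read_csv(path, dtype=str)
    missing = {"patient_id", "encounter_id", "admit_time", "icd9_code"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = frame.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: empty field at line {line}")
    return morbidity.records_from_frame(frame)


def write_morbidity_csv(data: MorbidityMatrix, path: str | Path) -> None:
    data.to_frame().to_csv(path, index_label="patient_id")


def read_morbidity_csv(path: str | Path) -> MorbidityMatrix:
    frame = pd.read_csv(path, index_col=0)
    return MorbidityMatrix.from_frame(frame)


def write_edge_list_csv(w: WeightMatrix, path: str | Path) -> None:
    """One row per unordered pair with nonzero weight (the canonical sparse
    interchange), 12 significant digits."""
    idx_i, idx_j = np.nonzero(np.triu(w.values, k=1))
    frame = pd.DataFrame(
        {
            "category_i": [w.categories[i] for i in idx_i],
            "category_j": [w.categories[j] for j in idx_j],
            "weight": w.values[idx_i, idx_j],
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")


def read_edge_list_csv(
    path: str | Path, categories: list[str] | None = None, method: str = ""
) -> WeightMatrix:
    frame = pd.read_csv(path, dtype={"category_i": str, "category_j": str})
    if categories is None:
        categories = sorted(set(frame["category_i"]) | set(frame["category_j"]))
    col = {c: k for k, c in enumerate(categories)}
    vals = np.zeros((len(categories), len(categories)))
    for _, row in frame.iterrows():
        i, j = col[row["category_i"]], col[row["category_j"]]
        vals[i, j] = vals[j, i] = row["weight"]
    return WeightMatrix(values=vals, categories=categories, symmetric=True, method=method)


def write_matrix_csv(w: WeightMatrix, path: str | Path) -> None:
    pd.DataFrame(w.values, index=w.categories, columns=w.categories).to_csv(
        path, index_label="category", float_format="%.12g"
    )


def write_graphml(
    w: WeightMatrix, path: str | Path, partition: dict[str, int] | None = None
) -> None:
    """GraphML export (Gephi-compatible); an optional modularity partition
    becomes a node attribute ``modularity_class``."""
    g = analysis.to_graph(w, drop_isolated=True)
    if partition is not None:
        nx.set_node_attributes(
            g, {n: int(partition.get(n, -1)) for n in g.nodes}, "modularity_class"
        )
    nx.write_graphml(g, path)


def write_network_csv(net: IsingNetwork, edges_path: str | Path, thresholds_path: str | Path) -> None:
    """Serialize a generative network as an (i, j, weight) edge list plus a
    per-node threshold table."""
    iu = np.triu_indices(net.p, k=1)
    nz = net.weights[iu] != 0
    pd.DataFrame(
        {"i": iu[0][nz], "j": iu[1][nz], "weight": net.weights[iu][nz]}
    ).to_csv(edges_path, index=False, float_format="%.12g")
    pd.DataFrame({"node": np.arange(net.p), "threshold": net.thresholds}).to_csv(
        thresholds_path, index=False, float_format="%.12g"
    )


def read_network_csv(edges_path: str | Path, thresholds_path: str | Path) -> IsingNetwork:
    thr = pd.read_csv(thresholds_path)
    p = len(thr)
    w = np.zeros((p, p))
    edges = pd.read_csv(edges_path)
    for _, row in edges.iterrows():
        i, j = int(row["i"]), int(row["j"])
        w[i, j] = w[j, i] = row["weight"]
    return IsingNetwork(weights=w, thresholds=thr["threshold"].to_numpy())


def read_scenario_toml(path: str | Path) -> list[ScenarioSpec]:
    """Scenario configuration: a [[scenario]] array with fields p, n,
    sparse_rate and optionally replicates, master_seed, n_sweeps and an
    estimators list of {method, alpha} tables."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    specs = []
    for sc in doc.get("scenario", []):
        ests = tuple(
            EstimatorSetting(e["method"], e.get("alpha")) for e in sc.get("estimators", [])
        )
        kwargs = {k: sc[k] for k in ("replicates", "master_seed", "n_sweeps") if k in sc}
        if ests:
            kwargs["estimators"] = ests
        specs.append(ScenarioSpec(p=sc["p"], n=sc["n"], sparse_rate=sc["sparse_rate"], **kwargs))
    if not specs:
        raise ValueError(f"{path}: no [[scenario]] entries")
    return specs


def run_pipeline(
    encounters_csv: str | Path, config: PipelineConfig, outdir: str | Path
) -> dict:
    """Full analysis: preprocess -> estimate -> symmetrize (graphical) ->
    positive filter -> summarize / degree tables / top edges / modularity.

    Writes all outputs plus a manifest recording configuration, seeds and
    versions under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_encounters_csv(encounters_csv)
    records = morbidity.select_last_encounter(records)
    data, exclusions = morbidity.build_matrix(records, min_count=config.min_count)
    logger.info(
        "morbidity matrix: %d patients x %d categories (%d categories, %d rows dropped)",
        data.n, data.p, len(exclusions.dropped_categories), len(exclusions.dropped_rows),
    )
    write_morbidity_csv(data, outdir / "morbidity_matrix.csv")
    (outdir / "exclusions.json").write_text(json.dumps(exclusions.to_dict(), indent=2))

    if config.method == "graphical":
        cfg = graphical.ElasticNetConfig(alpha=config.alpha, gamma_ebic=config.gamma_ebic)
        weights = graphical.symmetrize_min_abs(graphical.fit_network(data, cfg))
    elif config.method == "pairwise":
        weights = baselines.fit_pairwise_or(data)
    else:
        weights = baselines.fit_mutual_information(data, seed=config.seed)
    write_edge_list_csv(weights, outdir / "weights_edges.csv")
    write_matrix_csv(weights, outdir / "weights_matrix.csv")

    summary = analysis.summarize(weights)
    filtered = analysis.positive_filter(weights, min_logor=config.positive_threshold)
    by_unw, by_w = analysis.degree_tables(filtered)
    pos, neg = analysis.top_edges(weights, config.top_k)
    by_unw.to_csv(outdir / "top_nodes_unweighted.csv", index=False)
    by_w.to_csv(outdir / "top_nodes_weighted.csv", index=False)
    pos.to_csv(outdir / "top_edges_positive.csv", index=False)
    neg.to_csv(outdir / "top_edges_negative.csv", index=False)

    partition = None
    if filtered.edge_count() > 0:
        part = analysis.modularity_partition(filtered, seed=config.seed)
        partition = part.class_of
        pd.DataFrame(
            sorted(part.class_of.items()), columns=["category", "modularity_class"]
        ).to_csv(outdir / "modularity_classes.csv", index=False)
    write_graphml(weights, outdir / "network.graphml", partition=partition)

    manifest = {
        "comornet_version": __version__,
        "numpy_version": np.__version__,
        "input": str(encounters_csv),
        "config": asdict(config),
        "n_patients": data.n,
        "n_categories": data.p,
        "dropped_categories": len(exclusions.dropped_categories),
        "dropped_rows": len(exclusions.dropped_rows),
        "edge_count": weights.edge_count(),
        "graph_summary": summary.to_dict(),
        "modularity_classes": None if partition is None else len(set(partition.values())),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "graph_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    return manifest
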