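# comornet

Comorbidity network inference from electronic health record (EHR)
diagnosis tables.

Hospital encounter data record which diagnoses co-occur in the same
patient.  A *comorbidity network* turns this into a graph: nodes are
diagnosis categories, edges are statistical associations between them.
The classical way to build one is pairwise — an odds ratio and a Fisher
test per pair of diagnoses — but pairwise associations are confounded by
every other disease: obesity drives both diabetes and coronary artery
disease, so a pairwise network links the latter two even though they are
conditionally independent given the former.

`comornet` instead estimates the network as a binary Markov random field
(Ising model).  Each diagnosis is regressed on **all** other diagnoses
with an elastic-net penalized logistic regression,

    −(1/N)·loglik(β₀, β) + λ·( α·Σⱼ|βⱼ| + (1−α)/2·Σⱼβⱼ² ),

the penalty strength λ is chosen per node by the extended BIC
(eBIC = −2ℓ̂ + k·ln N + 2γ·k·ln p, γ = 0.25), and the resulting coefficient
matrix — entries are conditional log odds ratios (logOR) — is symmetrized
by the min-abs (AND) rule: an edge survives only if both of its two
nodewise regressions retain it, at the more conservative of the two
values.  Conditioning on all other diagnoses removes the confounded,
indirect edges the pairwise method keeps.

The package is written for biostatisticians and clinical informaticians
working with ICD-9-coded encounter tables (the MIMIC-style
`DIAGNOSES_ICD`/`ADMISSIONS` shape), and includes everything needed to
validate the estimator without access to protected data:

- `comornet.morbidity` — ICD-9 consolidation (3-digit / V+2 / E+3
  prefixes), last-encounter selection, rare-category filtering, binary
  patient x category matrix construction;
- `comornet.graphical` — the nodewise elastic-net estimator (fast
  numba-based coordinate descent), eBIC selection, min-abs symmetrization;
- `comornet.baselines` — pairwise odds-ratio (Fisher + Bonferroni) and
  mutual-information (permutation inference) networks;
- `comornet.ising` — ground-truth random networks and a Metropolis-
  Hastings Ising sampler (also the package's synthetic-data generator);
- `comornet.metrics` — Euclidean/Frobenius, Laplacian-spectral and
  NetSimile distances between estimated and true networks;
- `comornet.analysis` — density/transitivity/diameter/average-distance
  summaries, positive-edge filtering, top edges and nodes, Louvain
  modularity classes;
- `comornet.benchmark` — the six-scenario simulation comparison;
- `comornet.cli` / `comornet.io` — a `comornet` command with
  `preprocess`, `fit`, `analyze`, `simulate`, `bench` and `pipeline`
  subcommands, CSV/GraphML/JSON/TOML formats.

## Worked example

Simulate data from a known 8-node Ising network, recover it, and compare
with the pairwise baseline:

```python
import numpy as np
from comornet import ising, metrics
from comornet.baselines import fit_pairwise_or
from comornet.containers import as_weight_matrix
from comornet.graphical import ElasticNetConfig, fit_network, symmetrize_min_abs

net = ising.random_network(8, sparse_rate=0.3, seed=3)     # truth: 9 edges
data = ising.sample(net, n=500, n_sweeps=30, seed=4)        # 500 patients
truth = as_weight_matrix(net, categories=data.categories)

est = symmetrize_min_abs(fit_network(data, ElasticNetConfig(alpha=0.9)))
pw = fit_pairwise_or(data)

print("true edges:", net.n_edges)
print("graphical edges:", est.edge_count())
print("pairwise edges:", pw.edge_count())
print(metrics.distance_report(est, truth, "elastic_net_90").to_dict())
```

Output:

```
true edges: 9
graphical edges: 9
pairwise edges: 12
{'euclidean': 0.9772095224682562, 'spectral': 1.4471411383679669,
 'netsimile': 0.0, 'method_label': 'elastic_net_90'}
```

The graphical estimator recovers exactly the 9 true edges (NetSimile
distance 0: the estimated and true topologies are structurally
identical), and the Euclidean / weighted-spectral distances of ~0.98 and
~1.45 reflect the remaining error in the logOR weights at n = 500.  The
pairwise baseline keeps 12 edges — the 3 extra are marginal associations
transmitted through common neighbors.

On a real encounters CSV (columns `patient_id, encounter_id, admit_time,
icd9_code`) the whole pipeline is one command:

```sh
comornet pipeline encounters.csv --method graphical --alpha 0.9 --out results/
```

which writes the morbidity matrix, the edge list and full weight matrix,
graph summary statistics, top edges and nodes, modularity classes, a
Gephi-compatible GraphML file, and a manifest of every setting used.

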