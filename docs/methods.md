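# Methods

## The model

`comornet` treats a set of P binary diagnosis indicators as a binary Markov
random field (Ising model) on the {0,1} domain:

    P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} W_ij xᵢ xⱼ ),   x ∈ {0,1}^P

The interaction matrix W is the estimand: W_ij ≠ 0 means diagnoses i and j
are conditionally dependent given all other diagnoses, and W_ij is the
conditional log odds ratio.  The {0,1} domain (rather than {−1,+1}) is used
throughout because the full conditionals of this parameterization are
exactly logistic regressions of each node on all others, which is what the
estimator fits.

## Nodewise elastic-net estimation

For each category i the package minimizes

    −(1/N) Σₙ [ yₙ ηₙ − log(1 + e^{ηₙ}) ]
        + λ ( α Σⱼ |βⱼ| + (1−α)/2 Σⱼ βⱼ² )

with y the i-th column, covariates all other columns, and an unpenalized
intercept.  The ridge term carries the conventional 1/2 factor so that α
interpolates the penalty glmnet-style; "percent LASSO" settings 100/90/70%
map to α = 1.0/0.9/0.7.  Covariates are not standardized: all columns are
0/1 indicators on a common scale, and standardizing would reweight the
penalty by prevalence.

λ is selected per node by the extended BIC (Chen–Chen form)

    eBIC(λ) = −2ℓ̂ + k ln N + 2γ k ln p_cov

with k the number of nonzero coefficients and γ = 0.25, the convention of
the eLasso/IsingFit family of Ising model selectors; γ = 0 recovers
ordinary BIC.  The path is 100 log-spaced values from λ_max (the smallest
penalty that zeroes every coefficient, max_j |Σ xᵢⱼ(yᵢ−ȳ)|/(Nα)) down to
0.001·λ_max; ties in eBIC resolve toward the larger (sparser) λ.

The selected coefficient vectors fill the rows of an asymmetric P×P
matrix, which is then symmetrized by the min-abs (AND) rule: each pair
(w_ij, w_ji) is replaced by the member with smaller absolute value.  An
edge therefore survives only if both regressions retain it, and the more
conservative estimate is kept.  On an exact magnitude tie with conflicting
signs the row-major (i<j) entry wins; this situation is logged and, with
continuous data, has probability zero.

### Solver

The penalized fits use a hand-written proximal-Newton coordinate-descent
solver (an outer IRLS loop around cyclic soft-thresholding on the weighted
quadratic approximation, warm-started along the path).  Two structural
facts are exploited: binary covariates make every per-coordinate sum a
gather over a precomputed column index list, and new coordinates enter the
working set through a single BLAS vector-matrix KKT screen rather than
full cyclic passes.  Convergence uses the glmnet metric (largest weighted
squared coefficient change per pass) at tolerance 1e−7; coefficients are
exact zeros by soft-thresholding, with a final 1e−8 clean-up threshold.
IRLS weights are floored at 1e−5 for numerical stability.  The solver is
cross-checked in the test suite against scikit-learn's saga solver on the
same objective (agreement to ~1e−3 at saga's practical accuracy).

## Baselines

*Pairwise OR*: for each unordered pair, a 2×2 contingency table, weight
ln(ad/bc), two-sided Fisher exact p (the sum of all table probabilities no
larger than the observed one), Bonferroni correction over the actually
tested pairs (zero-variance columns are skipped with a warning and do not
count toward the correction denominator), and zeroing of weights with
adjusted p ≥ 0.05.  Tables with a zero cell use the Haldane–Anscombe +0.5
correction on all four cells by default; this keeps weights finite but
makes the pairwise method's large-scale distance values sensitive to how
many near-deterministic pairs the data contain, so a "drop" policy is also
available.  Non-significant entries are zeroed before any distance
computation.

*Mutual information*: weight = plug-in MI of the two binary columns in
nats; inference by permutation, p = (1 + #{MI_perm ≥ MI_obs})/(n_perm+1),
Bonferroni over pairs.  For binary columns a uniform shuffle induces an
exactly hypergeometric distribution on the both-present count, so
permutation draws are sampled directly as hypergeometric counts — identical
in distribution to materializing shuffled columns, and fast enough to use
large n_perm.  Margins are canonicalized (minimum of ones/zeros per
column) before drawing so the p-value is exactly invariant to relabeling
either column under a fixed seed.

## Simulation design

`ising.random_network(p, sparse_rate, seed)` draws each upper-triangle
edge independently with probability `sparse_rate`.  The generative model
is deliberately simple and fully documented because the benchmark numbers
depend on it:

- nonzero |W_ij| ~ Uniform(0.5, 1.5); sign positive with probability 0.9
  (comorbidity networks are predominantly positive, with a minority of
  structural exclusions);
- thresholds τᵢ = −(Σⱼ max(W_ij, 0))/2, which centres node prevalences
  near one half and avoids degenerate all-0/all-1 columns.

Sampling is single-site Metropolis–Hastings: each emitted row is an
independent chain started from a uniform random state and run for
`n_sweeps` full sweeps (default 100; sites visited in order, proposal =
flip, acceptance min(1, e^Δ), local fields maintained incrementally).
Per-row RNG streams are derived from one master seed, so output is
bit-identical across runs.  Correctness is verified against full 2^P
enumeration for small P (total-variation distance < 0.02 at 50,000
samples); the enumeration routine refuses P > 15.

What the generator does *not* emulate: real EHR prevalences are highly
skewed (most categories are rare), dependencies are not exactly pairwise
(higher-order clinical structure exists), and coding practice induces
measurement error.  Passing benchmarks therefore demonstrate estimator
correctness under a known sparse pairwise-interaction truth, not clinical
validity on any particular EHR.

## Distances

- Euclidean: Frobenius norm of the difference of the full symmetric
  matrices (both off-diagonal copies contribute; the upper-triangle
  convention would divide by √2).  Compares labeled matrices, so it is not
  permutation-invariant.
- Spectral: ℓ₂ distance between sorted eigenvalue spectra of the
  combinatorial Laplacians of the *weighted* graphs (absolute weights, so
  the Laplacian stays positive semidefinite).  The weighted convention is
  the default because the binarized spectrum is bounded by twice the
  maximum degree, which compresses exactly the large estimation errors —
  inflated weights on spurious dense edges — that this metric is meant to
  expose; `binarize=True` compares pure topologies instead.
- NetSimile: 7 node features (degree; clustering; mean neighbor degree;
  mean neighbor clustering; ego-net internal edge count; edges leaving the
  ego-net; distinct outside neighbors of the ego-net) × 5 moment
  aggregators (mean, median, SD, moment skewness, non-excess kurtosis;
  zero-variance features contribute 0 skew/kurtosis), compared by Canberra
  distance with 0/0 terms contributing 0.

## Graph analytics

Summary statistics are computed on the unweighted graph of nonzero edges
restricted to non-isolated nodes; diameter and average distance are taken
over the largest connected component (a finite diameter requires a
connected-subgraph convention), with the component count reported
alongside.  The positive filter keeps entries ≥ 1 logOR (inclusive).
Weighted degree is the sum of incident absolute weights (the Gephi
convention).  Modularity classes come from Louvain community detection
(networkx implementation) with a fixed default seed 0; weights must be
nonnegative, so partitioning is applied after the positive filter.

## Benchmark scales

The canonical comparison grid is 100 nodes × n ∈ {5000, 10000} × sparse
rates {0.05, 0.1, 0.2}, methods pairwise OR and elastic net at
100/90/70% LASSO.  Routine runs use a reduced grid (50 nodes,
n ∈ {1000, 2000}) with 5 replicates aggregated by median; replicate counts
are a package choice — single runs are reported at full scale, where the
between-replicate spread is modest relative to the factor-level contrasts
of interest.  The mutual-information baseline is only run on small
networks (20 nodes) because its permutation inference is the most
expensive step at scale.

## Known limitations

- The estimator returns conditional associations, not causal effects.
- ICD-9 only; no demographic covariates; no phenotype validation — the
  matrix builder trusts the codes it is given.
- The eBIC γ, the generator's weight distribution, and the
  binarize-before-spectral choice are conventions; all are configurable
  and the benchmark numbers should be read relative to them.
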