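# Methods

This note documents the statistical models, algorithmic choices and known
limitations of `metamodule`, in the spirit of the methods documentation of
packages like statsmodels or msprime. It states no empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## The setting

k independent two-group expression studies (high vs low phenotype; the
motivating application contrasts high and low bone mineral density in women)
measure overlapping gene universes on log2-normalized arrays. Single studies
are underpowered and tissue-biased; the goal is (i) per-gene meta-analysis
across studies and (ii) a *consensus functional module*: a connected
subnetwork of a PPI graph whose members carry jointly significant,
resampling-stable differential expression.

## Per-study score: SAM

For gene g, `d_g = (x̄_high − x̄_low) / (s_g + s0)`, where `s_g` is the
pooled two-sample standard error of the mean difference (the equal-variance
t denominator) and s0 a variance-stabilizing constant. With s0 = 0, d is
exactly the two-sample t statistic — a property the tests exploit as an
oracle.

* **s0 default**: the 5th percentile of the gene-wise standard errors. The
  classic coefficient-of-variation tuning is available behind `s0="tune"`,
  but the source analyses of this design rarely state their tuning rule, so
  a fixed percentile keeps runs reproducible and comparable.
* **Permutation null**: group labels are permuted `n_perm` times (default
  1000) and the null |d*| scores of *all* genes are pooled into one
  reference distribution. p_g = (1 + #{|d*| ≥ |d_g|}) / (1 + n_perm·n_genes).
  Pooling is what makes p-values far below 1/n_perm resolvable — with 2,000
  genes and 1,000 permutations the floor is ≈ 5·10⁻⁷ — and the plus-one
  smoothing keeps p > 0 so that `ln p` in Fisher's statistic is always
  finite. The trade-off: genes share a null, so p-values are weakly
  dependent and gene-specific variance structure is averaged over. Null
  calibration is checked empirically (KS uniformity at 2,000 genes).

## Meta-analysis

* **Fisher**: `χ² = −2·Σ ln pᵢ ~ χ²(2k)` under the null. Inputs are the SAM
  permutation p-values.
* **Effect sizes**: Cohen's d per study with Hedges' small-sample correction
  `J = 1 − 3/(4(n₁+n₂−2) − 1)`; variance
  `J²·[(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2))]`. The correction matters at the
  group sizes this design sees (n as low as 9–14) and can be disabled via
  `hedges=False`. The d inside the variance term is the uncorrected value,
  the standard Hedges form.
* **Heterogeneity gate**: Cochran's Q and I² = max(0, (Q−(k−1))/Q)·100
  (defined 0 at Q=0). Random effects (DerSimonian–Laird
  `τ̂² = max(0, (Q−(k−1))/(Σw − Σw²/Σw))`) when the Q-test p < 0.05 *or*
  I² > 50%; fixed effects otherwise. Both conditions are implemented exactly
  as stated; the gate is tested on constructed cases.
* **z p-value**: two-sided normal tail on z = pooled SMD / SE. A permutation
  alternative exists in principle (resample, re-pool, compare z), but the
  asymptotic normal is the default: at k ≥ 4 studies the pooled z is close
  to normal, and the permutation variant multiplies the pipeline cost by the
  permutation count for little calibration gain at these sizes.
* **FDR**: Benjamini–Hochberg step-up (via statsmodels), applied separately
  to the Fisher and effect-size p-value families.

## BUM scoring and module search

The Fisher-combined p-values of all common genes are fitted by the
beta-uniform mixture `f(p) = λ + (1−λ)·a·p^{a−1}` (λ, a ∈ (ε, 1−ε),
ε = 10⁻⁵) by L-BFGS-B with an analytic gradient from a 4×4 grid of starts;
the best log-likelihood wins. "Binomial uniform mixture" in the motivating
literature is read as this beta-uniform mixture — the only decreasing
density family the cited module-detection method defines over p-values.

At FDR level `fdr` (default 0.001), the score threshold is
`τ = ((π̂ − fdr·λ̂)/(fdr·(1−λ̂)))^{1/(â−1)}` with `π̂ = λ̂ + (1−λ̂)·â`, and the
node score is `S(p) = (â−1)·(ln p − ln τ)`: positive below τ, negative
above. Network nodes without a measured p-value receive S(1), the most
negative attainable score. Note an interaction to be aware of: τ can fall
below the permutation p-value floor when n_perm·n_genes is small, starving
the scorer; at the default scales (≥ 2,000 genes, 1,000 permutations,
FDR 0.001) the floor sits well below τ. Unit tests at smaller scales use
FDR 0.01 for this reason.

**Exact solver.** The maximum-scoring connected subgraph problem is solved
exactly by branch-and-bound over rooted connected-subset enumeration with
two provably safe reductions applied first: edges between two
positive-scoring nodes are contracted (any optimal solution containing one
endpoint absorbs the other), and negative leaves are peeled (a degree-1
negative node can never pay for itself). The bound adds all still-available
positive scores to the current subset score. Exactness is verified against
exhaustive enumeration of connected subsets on random ≤15-node instances.
The default exact-size limit after reduction is 30 nodes; beyond it the
package errors (if `method="exact"`) or falls back to the heuristic
(`method="auto"`). No external ILP backend is required.

**Heuristic.** Maximal positive-score components are contracted; starting
from the best one, other positive components are merged greedily when the
component's score exceeds the cheapest node-weighted (Dijkstra) connector
path penalty; finally negative, non-articulation nodes are pruned while
that improves the score. The result is always connected and never scores
below the best single node; it is bounded above by the exact optimum (also
verified by test).

## Consensus procedure

Each of `n_iter` iterations resamples every study — stratified bootstrap
within phenotype groups by default, preserving group sizes — and reruns
SAM → Fisher → BUM → module search at the same FDR. Node and edge
occurrence counts over the iteration modules become frequencies; the
consensus node score is `frequency − φ` (φ default 0.5) and the final
module is the maximum-scoring subnetwork under these scores (allowed to be
empty when nothing recurs more often than φ).

Two deliberate readings of ambiguous design points:

* **Bootstrap, not label permutation, as the default resampler.**
  "Resampling the case/control labels" could mean either; but permuting
  labels nullifies all group signal, and a consensus over null modules
  cannot contain reproducible signal. The signal-preserving stratified
  bootstrap is the only reading consistent with a signal-bearing consensus
  module; `resample="permute"` is provided for null calibration, and
  `resample="none"` gives the degenerate single-run collapse used in tests.
* **Consensus score = frequency − φ.** Any monotone transform of the
  frequency would do; this linear form makes φ an interpretable "minimum
  reproducibility" threshold and is exposed in the configuration.

Failures inside an iteration are logged and skipped; more than 50% failures
aborts the run. All randomness flows from one seeded generator, so runs are
bit-reproducible.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated:

* Baseline log2 expression: gene mean ~ N(7, 1.5²), within-group SD ~
  U(0.3, 1.0) — a realistic post-normalization microarray dynamic range.
* DEGs: a fraction `deg_fraction` of genes get a true SMD with magnitude
  uniform in `smd_range` (the published candidate table spans ≈ 0.45–0.70
  in magnitude, motivating the default (0.4, 0.8)) and random sign; the
  per-study SMD adds N(0, τ²) heterogeneity *on the SMD scale*, so Q and I²
  behavior is directly controllable.
* Defaults emulate the motivating six-cohort design: k = 6 with per-group
  sizes (40,14,10,45,10,10)/(40,12,9,39,10,10); optional two-platform
  dropout removes disjoint 10% gene sets from alternating studies to
  exercise gene-universe intersection.
* Network: Barabási–Albert preferential attachment (`networkx`), no
  self-loops. The planted module genes are mapped onto the first
  `planted_module_size` nodes of a BFS from a random vertex, so the module
  is connected *by construction without adding edges* and the closed-form
  BA edge count (n − m)·m is preserved. Planted genes are always DEGs; a
  zero `deg_fraction` yields an empty DEG set and an empty planted module
  (the no-signal configuration).

What the generator does **not** emulate: probe-level effects and RMA,
realistic PPI topology beyond scale-free attachment (no cliques/complex
structure), correlated expression between interacting genes, confounders
(age, menopausal status), or array-specific noise. Passing tests therefore
demonstrate the statistical machinery under idealized Gaussian conditions,
not performance on real cohort data.

## Validation scales

The recovery experiment runs 4 studies of 30+30 samples, 2,000 genes, a
500-node network with a 12-gene planted connected module at SMD 0.8
(τ² = 0.02, a mild heterogeneity consistent with the generator default),
20 consensus iterations of 1,000 permutations each — a scaled-down analogue
of the motivating 6-study, 13k-gene, 10k-node, 100-iteration analysis,
chosen so the whole validation remains a desk-scale computation. Null
calibration uses the same shape with no DEGs. Headline counts of the
motivating study (13,341 common genes; the 58-node/83-edge module; specific
pathway p-values) require the original data and curated PPI and are out of
scope; the package instead verifies the *analytic* consistency of the
published candidate-gene table (χ² tails at the printed Fisher statistics;
z vs SMD/SD ratios) from its printed values.

## Numerical details and edge cases

* IQR for probe collapsing uses linear-interpolation (type-7) quantiles;
  IQR ties keep the lexicographically smaller probe ID.
* Outlier screening: robust z = |x − median| / (1.4826·MAD) on PC1/PC2;
  zero deviation scores 0 even at MAD 0; removals that would leave a group
  below 2 samples are suppressed and logged. The published per-study
  outlier counts are not reproducible without the raw data; the robust-z
  rule is this package's own operationalization of the usual
  PCA-plus-clustering screen, which the original description leaves
  unspecified.
* `smd_per_study` raises on zero pooled SD for scalar input and flags the
  gene with NaN in vectorized use; genes with fewer than two valid studies
  get NaN meta-effect fields.
* BUM threshold: the raw τ is clipped into (0, 1); the formal degenerate
  condition π̂ ≤ fdr·λ̂ cannot occur for parameters inside the unit interval
  but is guarded defensively.
* All empty-input, out-of-range-p and disconnected-graph conditions raise
  `ValueError` with actionable messages.

## Known limitations

* The pooled permutation null assumes genes are exchangeable under the
  null; strong gene-wise variance heterogeneity with small s0 can distort
  calibration (mitigated by the s0 offset).
* DerSimonian–Laird τ̂² is noisy at k ≤ 3; the random-effects gate can
  misfire at very small k.
* The heuristic solver carries no approximation guarantee beyond the
  single-node lower bound; on adversarial topologies it can miss distant
  positive clusters.
* Consensus frequencies are estimated from `n_iter` resamples; at small
  `n_iter` the φ threshold is coarse (steps of 1/n_iter).
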