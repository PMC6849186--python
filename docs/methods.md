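# Methods

## Computation model

Every numeric method in this package is written against a single contract:
the input is a `ChunkedTable`, an ordered sequence of dense row blocks with
one shared column schema, and all data access happens by streaming those
blocks once per pass and reducing associative partial sums (counts, column
sums, cross-products, per-cluster weighted sums, weighted normal equations).
Two consequences are load-bearing and tested:

* **Partition invariance.** Any reduce-style statistic is identical (to
  floating-point reduction order, ≤ 1e-10 relative) however the rows are
  split into blocks. This is what makes the algorithms correct out-of-core:
  the chunking is an execution detail, not a modeling choice.
* **Memory contract.** No streaming operation materializes more than one row
  block plus O(p²) accumulator state (p = number of columns). The two
  exceptions are deliberate and documented: tree ensembles fit on the
  materialized *balanced* subsample (bounded by a 10⁶-row cap), and
  per-row assignment/score vectors of length n are held as single columns.

The container itself is an in-memory list of blocks at desk scale; the point
of the design is that every algorithm only ever touches it through the
streaming interface, so the same code runs unchanged over a lazily backed
partition source.

## Pipeline semantics

A config is expanded into a bipartite directed graph: places are data sets
(file-system paths), transitions are methods. Expansion rules: one
transition per dimension-reduction method reading the source table; one per
(dimension-reduction output × clustering method) pair, with the whole
`n_centers` sweep living inside that single transition; one per regression
method reading the source table. Hence
|triples| = |D| + |D|·|C| + |R|, verified exhaustively over method subsets.

Counting result sets follows the same rule — one result set per
(input, method) pair. With two reductions and two clusterers the clustering
stage yields four result sets and the dimension-reduction + clustering
stages together yield six; the two regression result sets are counted
separately.

A transition is enabled when its input place exists on disk; firing it
creates its output place (a result-set directory whose `params.txt` is
written last and serves as the completion marker). This gives idempotent
reruns (everything skips) and a `--force` flag to refire. The scheduler is a
deterministic Kahn ordering; independent triples are grouped into waves that
an optional process pool (`--workers N`) executes concurrently, each triple
receiving the derived seed `config.seed + plan index`. A failing triple
aborts its dependents but not independent branches.

Whether clustering may read the raw input directly (no interposed
reduction) was an open design point; it is supported — clustering
transitions fall back to the standardized source features — but the
canonical pipeline interposes a reduction, and that is the pattern the
acceptance suite exercises.

## Dimension reduction

Inputs are standardized (mean 0, variance 1, population convention) before
PCA, ICA and kernel PCA; FA and LDA only center, since their models estimate
per-feature scale themselves. Loading/unmixing columns are sign-fixed so the
largest-magnitude entry is positive, making results comparable across runs
and partitionings.

* **PCA.** Eigendecomposition of the streamed population covariance;
  components ordered by descending eigenvalue; scores are the centered data
  projected on the top-k eigenvectors. Variance shares are eigenvalues over
  their total and sum to 1 at full rank.
* **Factor analysis.** EM for x = Wz + ε, ε ~ N(0, diag(Ψ)). For this model
  the per-partition E-step reductions depend on the data only through the
  sample covariance S, so the package computes S in one data pass and runs
  the EM iterations entirely in p×p space — mathematically identical to
  reducing posterior moments partition-by-partition, with the bonus that
  iterations cost no further data passes. Initialization: W from PCA
  loadings scaled by √eigenvalues, Ψ from residual variances. Ψ is floored
  at 1e-6 to avoid Heywood collapse (tested on exactly low-rank data).
  Stops when the log-likelihood gain < 1e-4 (trace guaranteed
  non-decreasing; convergence flag false otherwise).
* **Kernel PCA.** The Gaussian kernel exp(−γ‖x−y‖²) is approximated by a
  seeded randomized trigonometric feature map z(x) = √(2/D)·cos(xΩ + b)
  with Ω ~ N(0, 2γI), b ~ U[0, 2π), followed by streaming PCA in the
  D-dimensional feature space. An exact n×n kernel matrix would contradict
  the chunked computation model. Defaults D = 200, γ = 1/p. The kernel
  approximation error decreases monotonically in D (tested at 8/64/512).
* **ICA.** Whitening to k dimensions via the PCA eigenbasis, then the
  fixed-point negentropy update with the log-cosh contrast; E[g(Wx)xᵀ] and
  E[g′(Wx)] are reduced per partition, and rows are re-orthonormalized by
  symmetric decorrelation (W W ᵀ)^(−1/2) W each step. Convergence when
  max |1 − |diag(W_new Wᵀ)|| < 1e-4. Near-Gaussian inputs (such as the
  simulated screen features) legitimately fail to converge; the flag
  reports it and the decomposition is still returned.
* **LDA.** One streaming pass accumulates per-class counts/sums and the
  total cross-product; S_w and S_b follow algebraically, and the directions
  solve the dense generalized eigenproblem (ridge 1e-6·tr(S_w)/p if S_w is
  singular). At most C−1 components for C classes.

## Clustering and model selection

* **k-means.** Careful (distance-proportional) seeding implemented as two
  streaming passes per center — one for the total squared-distance mass,
  one inverse-CDF walk — so memory stays O(K·p). Lloyd iterations reduce
  per-cluster sums and counts per partition and stop when the assignments
  stabilize; empty clusters are re-seeded from the farthest point. The SSE
  trace is non-increasing.
* **Gaussian mixture.** Diagonal-covariance EM initialized from a k-means
  fit (means, within-cluster variances, count weights). Responsibilities
  use log-sum-exp; variances are floored at 1e-6; a component whose weight
  collapses below 1e-8 is re-seeded from a random row. The log-likelihood
  trace is non-decreasing. Diagonal covariances are the default because
  full covariances at 43 features × 100 components are disproportionate at
  this scale.
* **BIC sweep.** Every K in `n_centers` is fitted and kept; best_K
  minimizes BIC, ties going to the smaller K. GMM: BIC = −2·loglik +
  [(K−1) + 2Kp]·ln n. k-means uses the classification-likelihood surrogate
  with a shared spherical variance σ̂² = SSE/(p(n−K)) and mixing terms
  Σ n_k ln(n_k/n), parameter count Kp + K. The mixing terms matter: a naive
  spherical BIC without them profits from splitting genuinely Gaussian
  clusters and over-selects K.

## Supervised learning

All supervised fits balance classes first by seeded downsampling of the
majority class to the minority count — equal prevalences by construction —
and report precision and recall on the full balanced data (no held-out
split; at the sample sizes the pipeline targets, train and test errors
coincide, and a test-fraction option remains available at the API level via
sampling). The classification threshold is fixed at probability 0.5, the
natural choice for balanced classes.

* **GLM.** Binomial IRLS: each iteration streams XᵀWX and XᵀWz and solves
  the dense (p+1) system; stop when the coefficient change < 1e-8. Features
  are standardized before fitting and coefficients are reported on the
  standardized scale (which is also the scale on which the generator's
  truth is defined). Standard errors come from the inverse observed
  information. |β| > 30 on standardized features flags likely perfect
  separation; a singular system falls back to a 1e-8 ridge. The Gaussian
  family reduces to streamed least squares.
* **Ensembles.** Random forest (Gini, √p features per split, depth ≤ 8) and
  gradient boosting (logistic deviance, depth-3 trees, learning rate 0.1),
  both defaulting to 20 trees and row-subsample rate 0.25; rate 1.0 uses
  the full sample exactly. They fit on the materialized balanced subsample
  and are backed by scikit-learn estimators behind this module's surface.

## Synthetic data

`simulate_screen` emulates the feature table of an image-based infection
screen: 43 features per cell in four named families (cell geometry, nucleus
geometry, perinuclear texture, neighborhood crowding/intensity), drawn as
zero-mean unit-variance Gaussians with within-block equicorrelation
(geometry 0.5, perinuclear 0.3, neighborhood 0.4, intensity independent) —
a one-time modeling choice giving realistic collinearity (VIF ≈ 2 for the
geometry block), not a claim about any real screen's marginals. The
infection label is Bernoulli with logit = intercept + 0.21·cell_area +
0.18·cell_perimeter − 0.11·n_neighbors; the intercept is solved by
Gauss–Hermite quadrature + root bracketing to hit the target prevalence
(default 0.3), erroring beyond |intercept| > 20. Everything is determined
by the seed; TSV output uses 6 significant digits.

What the generator does *not* emulate: skewed/heavy-tailed marginals,
plate/batch effects, spatial autocorrelation between cells, label noise
from imperfect pathogen staining, and the sheer scale of a real screen.
Passing recovery tests therefore demonstrates the correctness of the
algorithms under the stated model, not screen-level predictive performance;
the precision/recall printed on synthetic data characterize the generator's
signal strength, nothing more.

`simulate_factors` (x = Wz + ε with Gaussian or uniform unit-variance
sources) backs the FA/PCA/ICA recovery tests; `simulate_blobs` backs
clustering recovery.

## Problem sizes and determinism

Default validation sizes were chosen so each check is statistically decisive
yet quick: 500 cells for the end-to-end pipeline, 20 000 cells for GLM
coefficient recovery (3-SE bands ≈ ±0.08, well below the smallest true
effect), 5 000 rows for ICA, 600 for clustering recovery, 200–300 rows for
dense-oracle equivalence across ≥ 20 random partitionings. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`); pipeline
triples derive seeds as config seed + plan index, so reruns are
bit-identical on the same platform.

## Known limitations

* The chunked container is memory-backed; true disk-backed partitions would
  need only a different block source, but are not implemented.
* Kernel PCA offers the Gaussian kernel only, and no exact (Gram-matrix)
  mode; FA has no loading rotation; clustering offers no hierarchical or
  density-based methods.
* GMM covariances are diagonal by default; full covariances are not
  implemented.
* The Gaussian GLM family is supported but exercised far less than the
  binomial path.
* Empty-cluster re-seeding and degenerate-component re-initialization can
  break the monotonicity of the k-means SSE / GMM log-likelihood trace in
  the (rare, logged) iteration where they fire.
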