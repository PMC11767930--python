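# Methods

## The model

`cmtfomics` jointly factorizes two blocks of omics data that share their
sample mode: a 3-way tensor **T** of stratified microbial pathway
abundances (sample × microbe × pathway) and a matrix **M** of metabolite
intensities (sample × metabolite).

**Basic (shared-factor) model.** All latent factors are shared:

    T ≈ Σ_r a_r ∘ b_r ∘ c_r        M ≈ Σ_r a_r ∘ d_r

where `∘` is the outer product, `a` holds sample loadings (shared by
both blocks), and `b`, `c`, `d` hold microbe, pathway and metabolite
loadings. Fitting is alternating least squares (ALS): each factor
matrix in turn is the exact least-squares solution of its linear
subproblem, via Khatri–Rao-structured normal equations and a
pseudoinverse. The shared-mode update solves the *coupled* system

    a = [T(1)(c ⊙ b) + M d] (bᵀb ∗ cᵀc + dᵀd)⁺

(`⊙` Khatri–Rao, `∗` Hadamard, `T(n)` the mode-n unfolding in the
Kolda–Bader convention). A compatibility flag
(`FitConfig.coupled_a_update=False`) drops the `dᵀd` term from the
normal matrix; that variant is *not* the minimizer of the coupled
objective and is kept because it reproduces a historically used update
(see "Framework comparison" below). Iteration stops when the relative
change of the reconstruction RMSE (by default over the concatenation of
both blocks; configurable) falls below `tol` (default 1e-6).

**Weighted (advanced) model.** Each factor carries one weight per
block, so a factor can drive the microbiome block, the metabolome
block, or both:

    T ≈ Σ_r λ_r a_r ∘ b_r ∘ c_r        M ≈ Σ_r σ_r a_r ∘ v_r

The fitted objective is

    f = |T − T̂|² + |M − M̂|²
        + β Σ_r √(λ_r² + ε) + β Σ_r √(σ_r² + ε)
        + (α/2) Σ_{columns x of a,b,c,v} |x − mean(x)|²

The smoothed-L1 weight penalty (smoothing constant ε, default 1e-8)
shrinks block-specific weights toward zero and exposes unshared
factors; its gradient β·w/√(w²+ε) vanishes smoothly at the origin. The
column-centering penalty regularizes the offset indeterminacy of the
factors; its gradient is exactly α(x − x̄) because the centering
projector is idempotent. These two penalty forms were chosen so that
objective and gradient are mutually consistent — the load-bearing test
of the module verifies the analytic gradient against central finite
differences to < 1e-5 relative error. All parameters are flattened into
one vector and minimized with a quasi-Newton solver
(`scipy.optimize.minimize`; BFGS by default, any quasi-Newton method
accepted). Defaults α = 1, β = 1 are starting points, not validated
choices; both should be explored per dataset.

## Preprocessing

* **Logstack scaling** of stratified profiles: per (pathway, sample)
  cell with taxon contributions `y_t` and total `Y`, each contribution
  becomes `(y_t/Y)·log10(1+Y)` — the cell total is log-transformed
  while taxon proportions within the cell are preserved exactly.
  All-zero cells stay zero.
* **CLR** for metabolite intensities, per sample:
  `x → log(x+pseudo) − mean(log(x+pseudo))`; every output row sums to
  zero. When zeros are present the default pseudo-count is half the
  smallest nonzero intensity of the matrix (standard compositional-data
  practice to avoid −∞), overridable.
* **Subject collapsing**: repeated samples of a subject are averaged
  blockwise before the two blocks are joined, so unequal sampling
  depth per subject does not distort the coupling. The join on the
  shared mode is an inner join in sorted id order; absent
  (pathway, taxon) pairs are zero-filled.

## Rank selection by masked cross-validation

Entries are assigned to the test set independently with probability
`fraction` (default 0.2). Held-out entries are **zeroed** before the
ALS fit — this is deliberate and conflates "missing" with "true zero";
it keeps the training fit a plain ALS. An EM-style alternative that
iteratively imputes held-out entries with the current reconstruction is
available (`em_impute=True`) but off by default. Errors are
size-weighted relative squared errors:

    error = W_t·|ω_t∗(T−T̂)|²/|ω_t∗T|² + W_m·|ω_m∗(M−M̂)|²/|ω_m∗M|²

with `W_t = size(T)/(size(T)+size(M))`, `W_m = 1 − W_t` (test errors
use the complementary masks). No square root is taken; the API calls
the quantity an *error*, not an RMSE.

By default `cross_validate` warm-starts the fit at each successive rank
from the previous rank's factors plus one small random column (scale
1e-3). Because ALS never increases the objective, each larger model
then starts at least as good as the smaller one and the training-error
curve is non-increasing in R by construction — the qualitative pattern
expected of a nested model family. Cold starts (`warm_start=False`)
are available when independent fits per rank are wanted.

On structure-free data (every entry i.i.d. N(1,1)) the test error sits
above the training error and drifts upward with rank: added factors fit
only noise. This is the package's overfitting diagnostic.

## Group separation in latent space

Samples are projected onto the two factors with the largest explained
variance (share of the squared joint reconstruction norm). For two
groups of sizes s1, s2 the squared Mahalanobis distance between
centroids uses the pooled within-group covariance
`S = ((s1−1)S1 + (s2−1)S2)/(s1+s2−2)`:

    D² = (ȳ−x̄)ᵀ S⁻¹ (ȳ−x̄)
    F  = [(s1+s2−n−1)/(n(s1+s2−2))]·[s1·s2/(s1+s2)]·D²  ~  F(n, s1+s2−n−1)

with n = 2 (the projection dimensionality). This is exactly the
two-sample Hotelling T² test in its F form; under bivariate normality
the type-I error is calibrated (verified by simulation at α = 0.05).
Multi-group designs are handled pairwise. A singular pooled covariance
(e.g. a degenerate factor) raises an error rather than silently
regularizing.

## Biomarker ranking

Features of one mode are ranked by |loading| on one factor, signs
preserved (a negative loading means negative association with the
factor). Ties are broken by feature id for determinism. Against a set
of externally validated features, the top-k hit ratio is
`|top-k ∩ validated| / k`, and a full curve over k supports comparing
selection strategies.

## Synthetic designs

Two generators define the package's test conditions, both defaulting
to 40 samples × 50 microbes × 30 pathways with 20 metabolites:

* **Noise design**: every tensor and matrix entry i.i.d. N(1, 1) —
  no latent structure, used for the cross-validation diagnostic.
* **Weighted design**: factor matrices with entries i.i.d. N(1, 1),
  block weights λ = [1, 0.5, 1] (tensor) and σ = [1, 1, 0.5] (matrix)
  so the blocks do not share factors uniformly; an equal-weights
  variant sets λ = σ. Noise-free by default (`noise_sd=0`); ground
  truth is returned for recovery checks.

These generators emulate dimensionality and coupling structure only.
They are Gaussian, dense and noise-free — real microbiome data are
compositional, zero-inflated and overdispersed — so passing recovery
tests demonstrate correctness of the algorithms, not performance on
real data.

## Framework comparison on the weighted design

Two facts shape this comparison.

First, with the *corrected* coupled shared-mode update, basic ALS fits
the noise-free weighted design essentially exactly (relative error
~1e-30): the basic model can absorb λ into b and σ into d, so it is as
expressive as the weighted model on such data. Second, with the
*literal* update (normal matrix without `dᵀd`), the sweeps are not
exact minimizers; the error plateaus and the relative-change rule stops
the fit at a Frobenius residual of roughly 2–10 on this design. The
package therefore runs the comparison with the literal update on the
basic side — that is the algorithm historically used with this model —
and notes that the corrected update removes the gap entirely.

For the weighted fit, random-start quasi-Newton runs land in swamp
regions (slowly decreasing plateaus typical of collinear CP factors;
N(1,1) factor columns have expected cosine ≈ 0.7) for a substantial
fraction of starts. The replication runs therefore use the `init="als"`
option — a short coupled-ALS warm start, the standard initialization
for gradient-based coupled factorizations — after which the optimizer
reliably reaches a Frobenius residual of ~0.1–0.15 under the default
penalties, 15–60× below the stalled basic fit, for every seed tested.
Multi-start with random restarts remains the default for general use.

## Numerical choices

* Pseudoinverses (`numpy.linalg.pinv`) in all normal-equation solves;
  rank-deficient Gram matrices (e.g. all-zero data) yield zero updates
  instead of errors.
* Factor sign/order convention for reporting: components sorted by
  descending squared joint reconstruction norm; each sample column
  sign-flipped so its largest-magnitude loading is positive
  (compensated in b and d, leaving the reconstruction unchanged).
* ALS and the weighted fit are deterministic given a seed; the weighted
  fit draws restart seeds from one master generator.
* Degenerate inputs: relative errors on all-zero data, empty shared-id
  intersections, all-zero weight vectors and sub-minimum group sizes
  raise explicit errors.
* CP local minima exist even on noiseless data; roughly 1 random
  initialization in 10 hits one on small rank-2/3 problems. Recovery
  utilities and tests treat multi-start as the remedy.

## Problem sizes used by the shipped checks

The test suite and the results script run the weighted-design
comparison at the default 40×50×30 + 40×20 size (5 seeds distinct
weights, 3 seeds equal weights in the suite; one seed each in the
script), cross-validation over ranks 1–10 at the same size (10 seeds in
the suite), 2000 Monte-Carlo null draws for the separation-test
calibration, and small (≤ 12 per mode) instances for oracle and
gradient checks.

## Known limitations

* Dense tensors only; no sparse storage or out-of-core fitting.
* Missing data is handled by zero-masking (see above), not by weighted
  ALS.
* The weighted fit's α and β are not auto-tuned; cross-validation over
  them is left to the user.
* No metabolite pathway annotation and no built-in multi-group MANOVA;
  group tests are pairwise.
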