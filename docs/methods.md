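# Methods

## The model

A matrix-framed dataset **X** has I rows and K columns whose cells X_ik are
all of one kind: scalars, T×P multivariate time series (T may vary per
cell), or histograms.  The goal is a 2-D point Y_ik per cell such that
points of the same *row* group and the same *column* group stay close —
a biclustering-aware embedding.

Both margins get a classical t-SNE construction of their own:

* squared margin distances
  d(X_i·, X_j·)² = Σ_k d(X_ik, X_jk)² over rows and
  d(X_·k, X_·l)² = Σ_i d(X_ik, X_il)² over columns, where the element
  distance is |x−y| for scalars, the per-coordinate DTW summed in squares
  for series, and the L2-Wasserstein distance for histograms;
* Gaussian conditional affinities p_{j|i} ∝ exp(−d²/2σ_i²), with σ_i found
  by bisection on log σ so that the conditional's perplexity 2^H equals a
  target (entropy is monotone nondecreasing in σ, so bisection over
  σ ∈ [1e−10, 1e10] is exact to the stopping tolerance, default 1e−5 on the
  perplexity, 200 iterations max);
* symmetrized joints P_ij = (p_{j|i} + p_{i|j}) / (2n), total mass 1.

The low-dimensional side uses the Student-t kernel on *aggregated*
embedding distances: the row kernel is (1 + Σ_k ‖Y_ik − Y_jk‖²)⁻¹ and the
column kernel swaps the roles.  The objective is the convex combination

    C(Y) = α · KL(P^r ‖ Q^r) + (1 − α) · KL(P^c ‖ Q^c),   α ∈ [0, 1].

Neither KL term separates over elements, so each element is pulled by its
entire row and column.  The gradient of C is

    ∂C/∂Y_ik = 4α Σ_j (p^r_ij − q^r_ij) w^r_ij (Y_ik − Y_jk)
             + 4(1−α) Σ_l (p^c_kl − q^c_kl) w^c_kl (Y_ik − Y_il),

with w the unnormalized Student-t weights.  An alternative variant with
leading factors 4α² and 4(1−α)² is available
(`gradient_variant="as_printed"`); it is *not* the analytic gradient of C —
the finite-difference check in the test suite confirms the 4α/4(1−α) form —
so the cost-consistent variant is the default and the only one the
optimizer uses unless asked otherwise.

Two deliberate normalization choices:

* The conditional distribution is normalized per point (over j ≠ i for
  fixed i), the only form under which "the conditional achieves a target
  perplexity" is meaningful.  A pair-summed denominator variant is exposed
  (`pair_normalized=True` in `conditional_row`) for comparison but is used
  nowhere else.
* Independent row and column perplexities are the scale-adaptation
  mechanism: multiplying all data by a constant, or one margin's
  separations by 10×, changes only the calibrated σ's, not P.

## Optimization

Gradient descent with momentum: γ = 0.5 for the first 250 iterations, 0.8
after; learning rate η = 100; M = 1000 iterations; interior α initializes
Y with i.i.d. N(0, 1e−4²) coordinates (scale exposed; 1.0 available).
Two further pieces of the standard t-SNE recipe are on by default because
the plain momentum loop at η = 100 demonstrably oscillates after the
momentum switch (the cost rises back above its mid-run value and cluster
recovery fails on a fraction of seeds):

* per-parameter adaptive gains (Jacobs scheme: gain ×0.8 when gradient and
  velocity agree in sign, +0.2 otherwise, floored at 0.01);
* early exaggeration: P multiplied by 4 for the first 50 iterations.

Both are flags (`use_gains`, `early_exaggeration_*`) and can be switched
off to run the bare schedule.  The embedding is re-centered each iteration
(the cost is translation-invariant).  Runs are deterministic given the
seed; divergence (non-finite coordinates) raises an error naming the
iteration.  The recorded cost trace always uses the unexaggerated P.

### Boundary weights

α = 1 and α = 0 are exactly classical t-SNE on the row / column margin, and
are *run* as such: `matrix_tsne` dispatches to the classical engine on the
margin distance matrix and broadcasts the margin points across the
collapsed axis.  This is forced by the kernels: once all columns of a row
coincide, the aggregated row kernel becomes (1 + K·d²)⁻¹, which is not the
classical Student kernel on the margin — the coupled loop at α = 1 would
therefore *not* reproduce marginal t-SNE, while the definition of the
boundary cases says it must.  The dispatch makes the reduction exact
(trajectories coincide to machine precision with a classical run on the
same margin matrix and seed), which the acceptance suite checks
per-iteration.

### Complexity

One gradient evaluation costs Θ(IK(I+K)) multiply–adds (row term I²K,
column term K²I), versus Θ((IK)²) for classical t-SNE on the flattened
elements.  `gradient(..., count_ops=True)` tallies the dense tensor-op
sizes actually executed so the scaling can be measured rather than assumed.

## Weight selection

`select_alpha` implements the separability-driven search:

1. Marginal runs at α = 1 and α = 0 give I row points and K column points
   (exact duplicates across the collapsed axis are dropped).
2. G1 (rows) and G0 (columns) are the smallest g whose K-means partition
   has SSB/SST > 0.9, scanning g = 1..g_max (default min(n−1, 15); g = 1
   scores 0 by definition).  If nothing qualifies, g_max is returned with a
   flag.  Known group memberships bypass this step.
3. Cross-product labels over G = G0·G1 classes are the ground truth; each
   grid α (default 0.02..0.98 step 0.02 — fine enough to resolve two
   decimals) is scored on its embedding.  The default metric is SSB/SST of
   the cross-product labels on the I·K points, read directly off the
   partition the procedure just defined; ARI/NMI score a fresh K-means(G)
   against the cross-product labels instead (scikit-learn's implementations:
   permutation-model adjusted Rand, arithmetic-mean NMI).  A flag
   (`fresh_kmeans_for_ssb`) also re-clusters for the SSB/SST metric, since
   either reading of "separability at G clusters" is defensible.
4. α* is the argmax; ties resolve to the smallest α.

`seed_perturbation_eval` re-runs the embedding under several seeds and
tabulates ARI/NMI/SSB-SST per seed (optionally with the unstructured
baseline), summarizable to medians and IQRs.

## Distances

**DTW.**  Dynamic programming over the full alignment lattice (no window),
local cost |a_t − b_s|, two step patterns: `symmetric2` (diagonal step
weighted 2; the common default of the R implementation of record) and
`symmetric1` (all steps weight 1).  The origin cell contributes its local
cost once under both patterns, making dtw(s, s) = 0 and
dtw([x], [y]) = |x−y|.  Multivariate series are warped per coordinate
independently and the squared costs summed — the margin formulas consume
ΣDTW², not a joint multivariate alignment.  The DP kernel is JIT-compiled
(numba); the test oracle enumerates every monotone path exhaustively for
short sequences.

**L2-Wasserstein.**  With uniform density inside each bin, a histogram's
quantile function is piecewise linear in cumulative mass, so
∫(Q1−Q2)² dt is evaluated exactly on the merged breakpoint grid via the
closed form h/3·(d0² + d0d1 + d1²) per subinterval.  Endpoint values are
reconstructed from three interior evaluations per subinterval, so
zero-mass bins (jump discontinuities of Q at a measure-zero set of t) do
not contaminate the integral.  Zero-total-mass histograms are rejected at
construction.  Only order 2 is implemented.

**Margins vs elements.**  Margin matrices store *squared* distances (the
affinity formulas consume d²); the all-pairs element matrix for the
unstructured baseline stores unsquared distances (classical t-SNE
convention).  The optional `convex_distance_tsne` baseline feeds
α·d_r² + (1−α)·d_c² element-pair distances to a single classical run —
kept only as a comparison point, since one shared perplexity cannot adapt
to margin scale differences.

## Synthetic data

The generators plant an R×C checkerboard whose row and column effects are
additive (orthogonal in profile space), so each margin is independently
recoverable and the cross-product of marginal clusters is the element-level
truth.  Defaults mirror the planted scalar benchmark used throughout the
tests: I = 20, K = 18, R = 2, C = 3, separation 10, noise sd 1.

* Scalar: offsets are spaced so the minimum pairwise *margin profile*
  distance equals `separation` (row offsets separation/√K apart, column
  offsets separation/√I).  At separation 10 and unit noise the margin gap
  of 100 in squared distance stands ≈8 noise standard deviations above the
  within-group level — recoverable but not degenerate.  `row_scale`
  multiplies the row offsets only; at `row_scale=10` with separation 7 the
  element-level column spacing is ≈1.6 noise sd (heavily overlapped — an
  unstructured element embedding cannot see it) while the column margin
  gap is ≈3.9 sd of its own noise (comfortably recoverable by
  aggregation).  This is the scale-mismatch regime in which the structured
  method should dominate, and those two numbers are why the comparison
  fixture uses separation 7, noise 1, row_scale 10.
* Series: frequency (r+1 cycles) encodes the row group — a monotone
  warping cannot change cycle counts; phase 2πc/C encodes the column
  group; a random per-element shift of up to T/10 samples is warping noise
  DTW must absorb.  Amplitude is `separation`, noise additive.
* Histogram: B-bin histograms of n_samples Gaussian draws on one shared
  grid, means shifted by the row/column effects, width `sample_sd`.
  Finite sampling perturbs the Wasserstein distances at O(1/√n_samples);
  the bin count is a free parameter.

What the generators do **not** emulate: kinematic correlation between
joints, gene–gene covariance, long-run climate trends, unbalanced or
overlapping groups, missing cells, heteroscedastic noise.  Passing tests
show the method recovers *planted additive* structure under the stated
noise; they say nothing about robustness to correlated noise or
non-checkerboard structure.

## Numerical choices and degenerate inputs

* Conditional rows shift exponents by the row minimum before
  exponentiating (log-sum-exp guard); exact in exact arithmetic.
* Perplexity targets outside (1, n−1] are errors; degenerate equidistant
  rows accept any σ (the conditional is uniform at every bandwidth).
* SSB/SST with SST = 0 (all points identical) is an error in the ratio and
  a flagged g = 1 in the marginal scan; the ratio is clipped to [0, 1]
  against floating-point overshoot.
* K-means uses 20 restarts by default, seeded; ties in the α grid resolve
  to the smallest α.
* Histogram masses within 1e−6 of unit total are renormalized on load;
  larger deviations are errors.  Stored masses must sum to 1 within 1e−9.

## Problem sizes

The test and acceptance runs use the planted 20×18 benchmark (360 embedded
points, 10 seeds, full 0.02 α-grid), a 15×176 matrix (2 640 points) for
the point-count check, and sequences of length ≤ 6 / 50 histogram pairs
for the exhaustive distance oracles.  These sizes keep the full suite in
the minutes range on a single core while leaving every statistical check
at 10 random restarts.

## Known limitations

* Dense exact affinities and gradients only — no Barnes–Hut/FFT
  acceleration; practical up to a few thousand elements.
* Embedding dimension is fixed at 2.
* The α search is a grid scan; no continuous optimization of α.
* K-means defines marginal clusters; non-spherical marginal structure can
  bias G0/G1 (alternative clusterers are deliberately out of scope).
* The `as_printed` gradient variant is provided for comparison but there is
  no setting in which it descends the stated cost exactly.
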