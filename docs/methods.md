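# Methods

This note documents the model as implemented, the numerical procedure, the
synthetic-data generators, and the choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model and estimation

Every view `X` (n samples × p features) carries a mean model sharing latent
scores `Z` (n × M):

* count views: `E(X_ij | Z_i) = [clr⁻¹(u_x + R_iΦ + Z_iᵀΓ)]_j s_i`, with
  `s_i` the per-sample observed total (sequencing depth), treated as a
  fixed ancillary constant, and `u_x = clr(π_indep)` the clr offset of the
  pooled composition (per-feature totals over the grand total, observed
  cells only);
* gaussian views: `E(Y | Z) = u_y + SΞ + ZΘ` with identity link, `u_y` the
  per-feature observed means.

Parameters solve quasi-likelihood estimating equations
`Σ_observed (∂E/∂κ)(x − E)/V[E] = 0`.  Missing cells are simply excluded —
valid under missing-at-random, and the reason no imputation or
complete-case step exists anywhere in the pipeline.

Variance models:

* Count views: `Var(X_ij) = v_m(π_ijm) · s_i` with `v_m` the
  abundance–variance trend, re-estimated for every dimension `m` from the
  feature-wise depth-weighted variances
  `Σ_i (x_ij − E_ij)² / s_i / (n_j − 1)` (observed cells; `n_j` the number
  of observations of feature j).  `v_m` is a cubic smoothing spline of log
  variance on log independence-model abundance with smoothing chosen by
  generalized cross-validation.  Three restrictions implement the
  "variance never drops below the mean" rule: features below the 10th
  abundance percentile are excluded from the spline and get the Poisson
  line `v(π) = π` exactly; the spline is anchored to pass through the
  Poisson line at that cutoff (a constant shift on the log scale, which
  keeps the trend continuous — for Poisson-like data the shift is ≈ 0);
  and all predictions are floored at `v(π) ≥ π`.  Outside the fitted range
  the spline is extended linearly with its boundary slope.  Trend
  re-estimation runs during the first `max_trend_iter` (default 5) passes
  of each dimension or until its predictions change < 1%, then freezes so
  the parameter iteration can converge tightly.
* Gaussian views: per-feature residual variances with the standard
  empirical-Bayes squeeze — moment matching of log sample variances to a
  scaled-F model gives a prior df `d0` and prior variance `s0²` (trigamma
  inversion by Newton); posteriors are `(d0·s0² + d_j·s_j²)/(d0 + d_j)`.
  When the observed spread of log variances is no larger than its sampling
  noise, `d0 = ∞` and all features collapse to the geometric-mean
  variance, so identical inputs stay identical.  Residual df are
  `n_j − 1 − (m + #confounder columns)`, floored at 1.

Identifiability restrictions: `ZᵀZ = diag(ψ)` with centered columns
(centering fixes the location left free by the restriction and makes
scores read as deviations from the average sample); per view
`Γ Ω Γᵀ = I` in a diagonal weighted inner product; constrained fits use
`Z = c Λ diag(a)` with `ΛᵀΛ = I`, zero-sum within each categorical dummy
block, continuous design columns centered and scaled to sd 1, and a free
positive per-dimension scale `a` (the analogue of ψ — the restrictions
alone would otherwise fix the signal strength).  Ω defaults to the
per-feature mean relative abundance under the independence model
(normalized to sum to p) for count views — down-weighting rare, noisy
features in the normalization — and to normalized inverse shrunken
variances for gaussian views; both are frozen at their dimension-0 values
and user-overridable.

Confounders are conditioned on before any latent dimension is estimated
and frozen afterwards.  With the offset frozen, the no-reference-level
dummy coefficients are fully identified; count views retain one gauge
constant per design column (the softmax is invariant to constant shifts),
pinned by feature-centering each coefficient row.

## The fitting algorithm

Dimensions are fitted one at a time and frozen, so lower dimensions never
depend on the total number requested.  Within a dimension the solver
alternates Fisher-scoring block updates:

1. shared scores (per-sample 1-D equations, stacked over views; in
   constrained mode the d-dimensional gradient system `cᵀU = 0`),
2. each view's loading row (diagonal expected-information steps).

Linear identifiability constraints (centering, orthogonality to previous
dimensions, the linearized normalization, zero-sum blocks, and — count
views — the softmax gauge direction `1`) are eliminated *inside* each
Newton step, so a fixed point solves the projected estimating equations;
the exact restrictions are re-imposed by projection after every pass to
remove second-order drift.  Starting values are deterministic: the top
singular pair of the variance-scaled working residuals (counts:
`clr((x + 0.5)/s)` minus the lower-dimensional predictor — the 0.5
pseudocount exists only here, never in the model).  Convergence is
declared on maximum absolute parameter change (`tol`, default 1e-6);
the reported "quasi-score" diagnostic is the Fisher-scaled projected
estimating function — the length of the full Newton step in parameter
units — which is the score measure commensurable with a parameter-change
tolerance (raw estimating functions scale with the counts).

Two safeguards matter in practice.  Count loading rows must carry the
gauge constraint: without it the diagonal-information update drifts along
the softmax-invariant ones direction and the renormalization turns that
null mode into a neutral cycle.  And because diagonal information ignores
the softmax's cross-feature coupling, each block's step is damped by 0.6
whenever it reverses direction against the previous pass (eased back
after 10 aligned passes); steps are also capped at `max_step` (default 1)
per entry.  A dimension whose score norm collapses (ψ ≈ 0) stops the
sequence early with a warning.  Fits are exactly reproducible: the
default path contains no randomness.

## Influence diagnostics

The estimating-equation form gives per-observation influence directly:
for the score `Z_im`, the equation is that sample's feature sum, so the
influence of cell (i, j) is `−J_i⁻¹ · contribution_ij` with `J_i` the
per-sample Jacobian — analytic for gaussian views, central differences
(relative step 1e-6) for count views, where hand-derived softmax Jacobians
are error-prone; the test suite asserts the two routes agree where both
exist.  Gradient influence uses the d × d Jacobian `cᵀ diag(J) c`.  Masked
cells have influence exactly zero.  View-wise totals of absolute influence
reproduce the view-comparison summaries.  The one-step approximation
tracks leave-one-out refits to within ~25% for the largest-influence cells
on small fits; it degrades when a single cell also moves the loadings
appreciably.

## Synthetic data

Two generators define the study conditions.

`simulate_parametric` (the benchmark generator): n = 40 samples in two
equal groups, p = 1000 features per view by default, a negative-binomial
count view and a gaussian view.  Feature parameters come from parametric
pools standing in for pools of real-data estimates: log-normal(0, 2)
relative abundances, Gamma(2, 0.25) NB dispersions (mean 0.5), log-normal
depths (mean 2·10⁴, log-sd 0.5), N(10, 2) gaussian means with
log-normal(−0.7, 0.4) sds.  10% of features are differentially abundant;
count views get fold change 4, gaussian means a ×1.1 shift (the
"0.1 fold change" read multiplicatively; configurable).  In compensation
mode the DA set splits in half: the smaller-mean half is multiplied by 4
and the larger-mean half scaled by the factor that keeps the total
expected abundance equal across groups, so non-DA relative abundances are
exactly unaltered (the larger-mean half is sent down so that factor stays
positive).  Truly correlated feature pairs are same-direction DA pairs,
within and across views.  `permute_views` reshuffles each view's rows
independently — per-view structure intact, cross-view alignment destroyed.

`simulate_from_latent` (the recovery generator) draws data directly from
the model form with known orthogonal scores (sd 3.0 and 1.8 by default,
a moderate and clearly two-dimensional latent signal chosen so that score
recovery at n = 40, p = 200 is informative rather than noise-dominated),
unit-norm zero-sum loadings, NB dispersion 0.3 and gaussian noise sd 0.5.

What the generators do *not* emulate: phylogenetic or co-occurrence
correlation between features (noise is independent across cells given the
latent scores), longitudinal designs, zero-inflation beyond what the NB
produces, and batch structure.  Passing tests therefore demonstrate
correctness of the estimator under the stated model and realistic
marginal parameters — not robustness to every real-data pathology.

## Known limitations

* The variance form `v(π)·s` is linear in depth.  Under strong per-cell
  overdispersion the true NB variance grows quadratically, so extreme
  depth outliers (e.g. one sample at 10× the median) are over-weighted
  and can rotate a fitted dimension; with correctly specified (Poisson)
  noise the fitted scores are insensitive to such rescaling, and the
  per-sample score equations are exactly depth-invariant given the other
  parameters.  Re-estimating the trend per dimension does not remove this
  because the trend depends on abundance only.
* For the same reason the trend cannot express per-feature dispersion
  heterogeneity (an explicit non-goal: the count model stays
  distribution-free).  Features whose dispersion sits above the trend at
  their abundance attract loading weight; on data whose only structure is
  iid overdispersed noise, a fitted dimension can therefore correlate
  mildly with the realized sample sums, which are driven by the same
  abundant high-dispersion features.  This vanishes for Poisson-like data
  and is dominated by genuine signal when any is present.
* Compositional feature loadings must be interpreted through two-feature
  links, never individually; no variance-explained percentages are
  reported anywhere, by design — multiplot axes are forced square instead.
* No standard errors or formal inference; no automatic choice of M; no
  sparsity. Alignment across views assumes shared sample identifiers.
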