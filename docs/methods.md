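# Methods

## Models

`unfoldirt` fits unfolding (ideal-point) item response models to ordered
categorical (Likert) responses.  All kernels share the proximity idea: the
probability of endorsing higher categories peaks where the latent trait
equals the item location and decays symmetrically with
|&theta;&nbsp;&minus;&nbsp;&delta;|.

**GGUM family.** For codes z = 0..C, M = 2C + 1, the generalized graded
unfolding model sets

P(z | θ) ∝ exp{α[z(θ−δ) − Σ_{k=0}^{z} τ_k]} + exp{α[(M−z)(θ−δ) − Σ_{k=0}^{z} τ_k]},

the two exponents being the latent "agree from below / agree from above"
responses.  τ_0 is not separately identified and is anchored at 0; the free
thresholds are τ_1..τ_C.  Constraint systems follow the usual eight-model
taxonomy: α ≡ 1 (UM1–UM4) or free (UM5–UM8); thresholds shared across items
(UM1/3/5/7) or item-specific (UM2/4/6/8); the unit-threshold variants
(UM1/2/5/6) replace Σ τ_k with a single term z(M−z)λ applied in both
exponents, exactly as written in the source parameterization (other
treatments sometimes differ in where λ enters; we implement the printed
form).  The latent variance is freely estimated for UM1–UM4 and fixed at 1
where α is free (UM5–UM8), which is required for identification.

**Luo's general family.** The category probability is a normalized product
of C binary operational probabilities
P_k = ψ_k(ρ_k) / (ψ_k[α(θ−δ)] + ψ_k(ρ_k)), with numerator
Π_{k≤z} P_k Π_{k>z} (1−P_k).  ψ is any nonnegative, symmetric function
increasing on the positive half-line; the five supported choices are
exp|x| (ALM), exp(x²) (SSLM), x² (PARELLA), cosh x (HCM) and the
category-indexed cosh ratio cosh[((2C+1)/2+1−k)x] / cosh[((2C+1)/2−k)x]
(GUM).  The threshold argument of ψ is ρ_k itself (not α·ρ_k); with this
form the binary sub-probability crosses 1/2 where α|θ−δ| = ρ_k.  We note
the alternative α-scaled reading exists in the literature; the unscaled
form is implemented throughout (generation, estimation, scoring), so all
internal comparisons are consistent.

**Multidimensional (between-item) variant.** θ−δ is replaced by the
weighted Euclidean distance sqrt(Σ_d [α_d(θ_d − δ)]²); each item loads on
exactly one dimension, the item location is shared across dimensions, and
thresholds are common within a dimension.  Identification fixes μ = 0 and
unit latent variances, with the pairwise correlations free.

**Fisher information** is computed from analytic derivatives of the log
category probabilities (for the product-form kernels,
∂ log num_z / ∂a_k = U_zk − P_k with a_k the binary log-odds).  PARELLA is
degenerate at θ = δ (the top category has probability one); the
information there is reported as +inf.

## Estimation

Marginal maximum likelihood with EM on a fixed quadrature grid.  Defaults:
50 equally spaced nodes on [−4, 4] for one dimension, 15 per dimension
(tensorized, 3375 nodes) for three; weights are the normal density at the
nodes renormalized to sum to one (Gauss–Hermite is available as an option
but the rectangular rule is the default, matching common practice for
these models).  Responses are collapsed to unique patterns with counts;
missing entries are skipped via the data indicator.

The E-step forms expected response frequencies r_izq from each pattern's
node posterior.  The M-step maximizes the complete-data log-likelihood
with bounded L-BFGS-B over all free item parameters jointly, using exact
analytic gradients (the blocks are separable across items except for
thresholds constrained equal, which simply sum their item gradients).
Free density parameters are updated in the same cycle by maximizing the
expected prior-mass term Σ_q R_q log w_q — a 1-D bounded search for σ²,
L-BFGS over the pairwise correlations (non-positive-definite proposals are
rejected) — which keeps every cycle a proper generalized-EM step, so the
observed log-likelihood is nondecreasing.

Convergence: largest absolute parameter change < 1e−4, at most 500
cycles.  Bounds: α ∈ [1e−3, 10], δ and τ/λ ∈ [−6, 6], ρ ∈ (1e−3, 6],
σ² ∈ [0.04, 9], correlations ∈ (−0.95, 0.95).  No ordering is imposed on
τ or ρ.  Per-node log-probabilities are floored at log(1e−300); a pattern
whose likelihood still underflows raises an error naming the pattern.

For the between-item multidimensional models the implementation exploits
the fact that an item's probabilities depend on a node only through its
coordinate on the item's dimension: probabilities are evaluated on the
15-point axis and the expected counts collapsed onto it before the
M-step.  This is exact (verified against the direct tensor-grid path) and
reduces the fit cost by roughly the number of off-axis nodes.

**Starting values.** α starts at 1; δ at ±1 using user-supplied item
polarity signs (the standard recommendation for unfolding models — sign
matters far more than magnitude) or a small seeded jitter; thresholds from
pooled category proportions (ρ_k = 2·P(Z ≥ k) clipped to [0.2, 2.5]; τ_k a
damped logit of the same proportions); σ² at 1 and correlations at 0.

**Degenerate solutions.** At small samples the unfolding likelihood for an
extreme item can drift along a δ/τ (or δ/α) ridge, with the genuine
maximum at the parameter bounds — the fitted peak escapes the latent
support and the item becomes effectively monotone.  Fits ending with an
estimate on a bound are flagged (`FitResult.boundary`); the recovery
harness treats them like non-convergence and discards/resimulates the
replication.  Interior ridge solutions are legitimate MLEs and are kept,
which makes small-sample max-over-items error summaries heavier-tailed
than those of software whose optimizer stalls before traversing the
ridge.

## Standard errors and scoring

Standard errors come from finite second differences of the observed-data
log-likelihood at the estimates, with relative steps 1e−4·max(1, |ξ|):
central differencing for unidimensional models, forward for
multidimensional (cost), and Richardson extrapolation of central
differences (4 levels) as the high-accuracy option.  SEs are
sqrt(diag((−H)⁻¹)); a non-positive-definite −H falls back to a
pseudo-inverse and is flagged rather than silently reported.

Person scoring: EAP (posterior mean over the grid, posterior SD as SE),
MAP and MLE (continuous optimization from the grid maximizer;
curvature-based SE).  The empirical reliability is
var(θ̂) / (var(θ̂) + mean(SE²)) — the source material does not print a
formula for this coefficient, so the standard EAP-based definition is
adopted.

## Synthetic data and the recovery harness

The generator reproduces three study designs on four-point items
(C = 3): δ equally spaced on [−2, 2] (per dimension for the 3-D design);
τ = (−1.10, −0.72, −0.30) or ρ = (1.102, 0.794, 0.587); α ≡ 1 or drawn
once from Uniform(0.76, 1.34) and held fixed across replications (so "max
over items" summaries refer to one truth; per-replication redraws were
also examined and give the same magnitudes); θ standard normal, or
trivariate normal with equicorrelation 0/.4/.8.  Each replication redraws
persons and responses with seed base+r.

Recovery metrics per parameter: bias = mean error, RMSE = root mean
squared error (the root is intended: SD = sqrt(RMSE² − bias²) must hold),
and RM = mean(SE)/SD − 1 for SE calibration (0 = well calibrated,
positive = overestimated).  Fits are aligned to the generating
orientation before scoring: every kernel is invariant under jointly
reflecting θ and δ (per dimension in the between-item design), so the
harness flips a fitted solution when its δ vector anticorrelates with the
truth, adjusting affected correlation signs.

## Problem sizes used by the shipped checks

The test suite and the acceptance script scale the Monte Carlo studies to
desk size as the package's own defaults: 25 replications for the
GGUM-family table comparisons, 100 replications for the headline GUM
(n = 1500) and UM8 (n = 250) studies, 25 per cell for the HCM/GUM grid,
10 for the three-dimensional designs (n = 500, 7 items per dimension,
correlation .4), and reduced replication counts (20 at n = 250, 8 at
n = 1500) for the SE-calibration runs, whose Hessians dominate the cost.
Comparisons against reference values use Monte Carlo tolerances: a
bootstrap SE of the computed summary combined with the reference run's
own sampling SE, and max-|bias| noise floors rescaled by sqrt(R_ref/R)
when replication counts differ.

## What the synthetic studies do and do not show

The generator draws exactly from the fitted model families with known
truth, normal traits and complete data.  Passing recovery checks
therefore demonstrates correctness and calibration of the estimation
machinery, not robustness to model misspecification, non-normal trait
distributions, missingness mechanisms, or real response styles.
Small-sample behavior of extreme items is intrinsically unstable for
these models; with n = 250 and 10 items, location errors above 1 unit for
low-discrimination extreme items are genuine features of the MLE, not
estimation failures.

## Known limitations

- Analytic Hessians of the complete-data objective are not implemented
  (quasi-Newton needs only gradients); observed-information SEs rely on
  numerical differencing.
- PARELLA's singular point (θ = δ) yields infinite information and
  unstable gradients in its neighborhood; estimation with PARELLA works
  but is not part of the headline studies.
- The multidimensional fast path assumes the between-item design on a
  rectangular tensor grid; within-item loading structures fall back to
  the general (slower) path only for probability evaluation, and
  estimation of within-item models is not supported.
- Exploratory (rotation-unconstrained) multidimensional estimation is out
  of scope; the loading structure must be supplied.
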