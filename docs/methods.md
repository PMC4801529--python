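# Methods

`bittertongue` calibrates an electronic-tongue (e-tongue) sensor array
against human taste-panel bitterness scores with a robust partial least
squares (PLS) regression, and classifies calibration samples into the
three outlier classes of the standard robust-regression outlier map.
This note documents the statistical model, the estimators, the synthetic
data the tests run on, and the numerical choices that were genuinely open.

## The calibration problem

A panel of trained assessors rates the bitterness of each liquid sample
(here: herbal decoctions) on a continuous 0.5–5.5 scale divided into five
ranks (I–V), each anchored by a berberine hydrochloride reference
solution.  The same samples are measured by an array of p = 7
cross-sensitive potentiometric sensors (ZZ, CA, DA, BA, GA, BB, AB); each
sensor is read over several acquisition cycles and the mean of the last
four per-cycle final values is the sensor's response.  The calibration
model maps the n × p response matrix X to the panel mean y:

    I = b₁·ZZ + b₂·CA + … + b₇·AB + b₀

Panel data are subjective and e-tongue runs can carry over residue from a
strongly bitter predecessor, so a minority of samples is expected to be
aberrant.  Ordinary least squares (MLR), classical PLS and kernel methods
all have a breakdown point of zero — a single sufficiently bad sample can
move them arbitrarily — which motivates the robust fit at the package's
core.

## Panel screening

Assessor-level scores are screened per sample with an iterative two-sided
Grubbs test: the most extreme score is removed while
G = max|xᵢ − x̄|/s exceeds the critical value
G꜀ = ((N−1)/√N)·√(t²/(N−2+t²)), t = t_{1−α/(2N), N−2},
with α = 0.05 by default and never fewer than 3 scores retained (G is
undefined below that; a zero-variance set is returned unchanged).  The
cleaned scores are reduced to mean ± sd (n−1 denominator) records.

## Robust moments: FAST-MCD and projection-pursuit PCA

The robust fit rests on the minimum covariance determinant (MCD): the
h-subset of observations whose covariance has minimal determinant, with
h = max(⌊αn⌋, ⌈(n+d+1)/2⌉) and coverage α = 0.75 by default (the
convention of the robust-statistics toolboxes this estimator family comes
from; the resulting breakdown point is ≈ 25%).

* `exact_mcd` enumerates all C(n, h) subsets (n ≤ 15) and is the oracle
  the scalable algorithm is tested against; determinant ties break toward
  the lexicographically smallest index set.
* `fast_mcd` is the standard C-step algorithm: 500 random (d+1)-point
  subsets (grown when their covariance is flat), two concentration steps
  each, the 10 best candidates iterated to a fixed point.  The C-step
  theorem guarantees a non-increasing determinant, which is asserted per
  iteration.  The raw scatter is multiplied by the asymptotic consistency
  factor α / F_{χ²_{d+2}}(q_{d,α}) so it is unbiased for the true scatter
  under Gaussian data, then refined by one reweighting pass at the 0.975
  χ² cutoff (with the matching 0.975 factor).  Without these factors the
  2.5σ residual rule and the χ² score-distance cutoff would not have
  their nominal false-positive rates.  Small-sample correction factors
  are not applied; the calibration tests below bound the residual bias at
  the sample sizes used.  If an h-subset covariance is singular, at least
  h points lie on a hyperplane and an exact-fit error carrying the
  degenerate direction is raised.
* `robpca` handles the n < p-safe reduction: project to the affine span,
  rank samples by Stahel–Donoho outlyingness along 250 random directions
  through point pairs, take the top-k eigenvectors of the covariance of
  the h least-outlying points, and run FAST-MCD on the scores inside that
  subspace.  Orthogonal outliers are visible in the outlyingness ranking
  (`h_subset`), not in the in-subspace MCD support — their projections
  onto the retained plane are unremarkable by construction.

All stochastic steps are driven by explicit seeds; bit-exact agreement
with any particular MATLAB implementation is a non-goal (agreement
targets are statistical and enforced by the test suite).

## The robust SIMPLS fit

`rsimpls_fit(X, y, k, alpha)` proceeds as:

1. Robust center μ and scatter S of the joined (X, y) block from `robpca`
   at full joint rank.
2. SIMPLS weight extraction from the robust cross-covariance S_xy with
   deflation of orthonormalized x-loadings, giving weights R (p × k) and
   scores tᵢ = Rᵀ(xᵢ − μ_x).
3. Score-space regression coefficients (RᵀS_xxR)⁻¹RᵀS_xy, mapped back to
   b = Rq with intercept μ_y − μ_xᵀb.
4. One reweighting pass: case weights are set to 0 for samples with
   |residual| > 2.5·σ̂ (σ̂ an LTS-style trimmed residual scale with its
   Gaussian consistency factor) or score distance above the rooted
   χ²_{k,0.975} quantile, and the score regression is refit by weighted
   least squares on the rest.
5. Outputs: coefficients and intercept in original sensor units, the
   robust residual scale s (weighted residual RMS with dof Σw − k − 1,
   corrected for the ±2.5σ trim), the robust score center μ̂_t and scatter
   Σ̂_t (moments of the retained scores, 0.975-truncation-corrected), and
   the 0/1 case weights.

`alpha = 1` switches every step to classical moments with all case
weights 1 — this is the "outlier fraction set to zero" mode used to
retrain on a cleaned dataset, and it makes the fit collapse exactly to
classical SIMPLS (and to MLR at k = p), which the tests exploit as an
algebraic anchor.

A property worth knowing: PLS with k < p is *not* equivariant under
column rescaling — the weight direction itself changes — so the familiar
"scale a column by 10, its coefficient divides by 10" identity holds only
at k = p.  Predictions on well-structured data are nearly unaffected
either way; the equivariance tests therefore pin the exact identity at
k = p.

## Choosing the number of latent variables

For k = 1…k_max the selection curve records the robust fit error R-RMSE
and the robust leave-one-out error R-RMSECV, both weighted by the case
weights of a robust fit at that k (the "R-" variants exclude the samples
the robust fit downweights).  They are blended by the robust component
selection statistic

    RCS_k = √(γ·R-RMSECV_k² + (1−γ)·R-RMSE_k²),  γ ∈ [0, 1]

so γ = 1 scores only prediction quality, γ = 0 only goodness of fit, and
γ = 0.5 weights them equally.  The statistic is computed under the square
root so its endpoints return the corresponding error term itself and the
value always lies between its two inputs.  Curves are reported for
γ ∈ {0, 0.5, 1}.  Because the original selection was made visually from
the curve's plateau, the plateau is made explicit here: the chosen k is
the smallest k whose relative RCS improvement to k+1 (at γ = 0.5) falls
below `plateau_tol` = 0.05; the argmin-RCS k is reported alongside.
LOOCV folds are reseeded deterministically as seed + fold index.

## Outlier map and exclusion policy

Each sample gets two coordinates:

* Sr = rᵢ/s, the standardized residual.  The standalone
  `standardized_residuals` uses the classical scale
  s = √(Σrᵢ²/(n−p−1)); the pipeline's `diagnose_model` standardizes by
  the model's robust residual scale instead, because a 10%-at-10σ
  contamination inflates the classical scale ~3× and would let gross
  outliers sit barely above the cutoff (outlier masking).  On clean data
  the two scales agree up to the consistency factor.
* SD = √((tᵢ−μ̂_t)ᵀΣ̂_t⁻¹(tᵢ−μ̂_t)), the score distance.  The rooted form
  is stored and compared against the rooted χ²_{k,0.975} quantile; the
  flag decision is identical to comparing squared distance against the
  squared cutoff.

Cutoffs: |Sr| > 2.5 (two-sided) and SD > √χ²_{k,0.975}.  The classes:
good leverage (SD only — far along the model line but consistent with
it), bad leverage (both), vertical (Sr only).  The default exclusion
policy drops bad-leverage and vertical samples and retains good-leverage
ones (they extend the calibration range and stabilize the slope); manual
include/exclude lists override per sample for borderline judgement calls.
Retraining on the retained set uses α = 1.

## Benchmarks

MLR (QR-based least squares, refusing rank deficiency), classical SIMPLS
(the α = 1 path), and an RBF-kernel least squares SVM whose training
solves the single linear system [[0, 1ᵀ], [1, K + I/γ_reg]]·[b; a] = [0; y]
with K(x, z) = exp(−‖x−z‖²/w); w is the *squared* length-scale.  Inputs
to the kernel are per-column z-scores of the training data (the raw-input
form is retained for the linear-system contract tests) so the joint
log-spaced default grid γ_reg ∈ 10^{−2..6}, w ∈ 10^{−2..4} is meaningful
at any sensor scale; grid points are scored by the exact closed-form LOO
residual aᵢ/(C⁻¹)ᵢᵢ and ties break toward the smaller γ_reg, then width.

Each method is scored by LOOCV: RMSECV and R²_CV (squared Pearson
correlation of held-out predictions with y, 0 with a flag when
degenerate).  The robust method is scored by the robust variants — the
case weights of a robust fit on the evaluation data exclude the samples
it flags — because the robust model declines to fit gross outliers by
design, and charging it for their prediction errors would measure the
opposite of what it promises.  The classical comparators are scored on
all samples.

## Synthetic data generator

No sensor matrix was ever published for the motivating study, so the
generator stands in for it with known ground truth:

* latent bitterness τ ~ Uniform(0.63, 4.78) — the observed range of the
  35-decoction panel; a Gaussian option with matched mean/variance exists
  because the diagnostic flag-rate calibration checks are statements
  about Gaussian tails (a uniform latent has none beyond 1.8 sd);
* sensors: X = baseline + loading·τ + N(0, σ_x), with baselines of order
  10³ and loadings of order 10², chosen so the fitted original-form
  coefficients are of order 10⁻⁴–10⁻³ against an intercept of order
  1–10, the conditioning a real e-tongue calibration has; σ_x = 20;
* response: y = τ + N(0, σ_y), σ_y = 0.2 — the panel-mean noise implied
  by per-assessor sds of 0.15–1.2 averaged over ~10 assessors, the
  spread the published panel records show;
* the population regression coefficients (the recovery oracle) follow in
  closed form from Sherman–Morrison:
  β = loading·var(τ)/(σ_x² + var(τ)‖loading‖²);
* replicate series add a geometrically decaying drift to the first 3
  cycles, so the stabilized-window mean is exact when noise is zero;
* contamination (exact counts, round(fraction·n), disjoint samples,
  refused at ≥ 50% total): vertical outliers shift y by magnitude·σ_y;
  bad-leverage points are displaced along the latent direction by
  magnitude clean column-sds with y left at its clean value (a
  displacement orthogonal to a rank-one design would leave both the
  calibration and the scores untouched — nothing would be damaged or
  detectable); good-leverage points extend τ beyond the design range by
  magnitude·σ_y with X and y following consistently, so a well-estimated
  slope still predicts them (a much larger extension would be flagged
  through slope-error amplification even for on-model points).
* default contamination mirrors the study's mix: one good-leverage
  sample, ~3 bad-leverage and ~2 vertical outliers per 35 samples at
  magnitude 10.

What the generator does not emulate: inter-sensor correlation beyond the
shared latent factor, pH effects, drift between (rather than within)
runs, non-linear sensor saturation, and panel score granularity.  Passing
tests therefore demonstrate the estimators' statistical properties under
the stated linear model, not instrument-specific behavior.

## Problem sizes and tolerances

The test suite and the acceptance script use n = 35–100 for calibration
runs, n = 200–500 for flag-rate calibration, 20 seeded replicates for
recovery medians, and n ≤ 12 instances for the enumeration oracle; these
sizes make every statistical check stable across seeds while keeping a
full run in the low minutes on one core.  Numerical tolerances: algebraic
identities (robust-at-α=1 vs MLR, SIMPLS-at-k=p vs MLR, equation round
trips) at 1e-8–1e-10; statistical targets at the bands stated in the
tests (e.g. clean-data SD-flag rate in [0.005, 0.08] around the nominal
0.025).  Degenerate inputs (zero-variance response, rank-deficient X,
singular scatters, all-zero weights) raise informative errors rather than
propagating NaNs.

## Known limitations

* The robust fit's coverage α, direction count and reweighting scheme
  follow robust-statistics toolbox conventions; the motivating study did
  not publish its settings, so exact numerical agreement with it is not
  expected (and its data are unavailable to check).
* The closed-form LSSVM LOO residual is exact for fixed preprocessing;
  with per-fold standardization it is an approximation used only for
  grid ranking (the reported final scores use true fold-by-fold refits).
* `exact_mcd` is combinatorial and deliberately refuses n > 15.
* The pipeline assumes a univariate response; multivariate panel
  attributes (e.g. astringency alongside bitterness) are out of scope.
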