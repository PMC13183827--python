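# Methods

## Design and data model

The unit of analysis is the plot of an augmented randomized complete
block design (ARCBD): a small set of check varieties replicated once in
every block, and unreplicated test entries (half-sib seedling progenies)
each planted in exactly one block per year. The plot model is

    Y_ij(k) = mu + beta_i + C_j + tau_k(i) + eps_ij,

with block effects beta_i, check effects C_j, test effects tau_k(i) and
plot error eps. Field books are plain CSV; validation enforces the
replication invariants strictly (every check exactly once per
year x block, every test in one block per year, check and test labels
disjoint). Missing trait cells are allowed; every stage operates on
complete cases per trait and logs the n used.

## Block adjustment and ANOVA

Block effects are estimated from checks only (Federer's method):
b_j = (mean of checks in block j) − (grand check mean), which sums to
zero over blocks. Adjusted test means are V_i = u_i − b_j; check means
are plain replicate means. This coincides exactly with the OLS fit of
the additive genotype + block model with sum-to-zero block constraints
(the unreplicated tests contribute nothing to block estimation), which
the test suite verifies against an independent least-squares oracle.

A consequence worth stating: adding a constant c to every plot of one
block moves *every* adjusted mean by exactly c/b (the grand check mean
absorbs c/b), so genotype differences and rankings are invariant but the
individual values are not. The property tests assert this exact law.

The ANOVA is sequential: genotypes ignoring blocks (sub-partitioned into
checks, tests, and tests-vs-checks, which sum exactly to the genotype
SS), then blocks eliminating genotypes, then a residual carried entirely
by check replication with (b−1)(c−1) df in a single year. F-tests use
the residual mean square; significance codes are NS / * (p<0.05) /
** (p<0.01). Precision statistics: CV% = 100·sqrt(MSE)/grand mean,
SE(m) = sqrt(MSE/b), and the headline critical difference uses the
test–test different-block standard error sqrt(2·MSE·(1+1/c)) with the
two-sided t quantile at the residual df; all four Federer standard
errors of a difference are emitted.

**Pooled ANOVA convention.** For a two-year trial the pooled ANOVA
stacks both years with composite year:block blocks. Each test then has
two observations, so the test-entry mean square estimates
2·sigma2_g + sigma2_gy + sigma2_e rather than a per-plot phenotypic
variance; the derived H2 is therefore a heritability of genotype means
across the two years, which is the quantity selection on pooled means
actually responds to. Per-year ANOVAs are also available, and the
recovery tests calibrate the per-year estimator. The residual df of the
pooled table follows from the stacked layout (N − g − b_stacked + 1);
we document this arithmetic explicitly because pooling conventions for
augmented designs vary between software packages.

## Pooling across years

Before pooling, Bartlett's chi-square test (with the standard correction
factor) is applied to the per-year check-residual vectors per trait;
scipy supplies the statistic, and an independent textbook-formula oracle
checks it in the tests. Pooling treats years as fixed and genotypes and
genotype-by-year as random. With one adjusted mean per genotype-year
cell the layout is balanced, so the expected-mean-squares (moment)
estimator coincides in expectation with REML and is used directly:
sigma2_gy = MS_GY (confounded with error at the adjusted-means level)
and sigma2_g = max(0, (MS_G − MS_GY)/y), floored at zero with a flag.

## Genetic parameters

sigma2_p is the test-entry mean square, sigma2_e the residual mean
square, sigma2_g their difference (reported NA when non-positive, as
happens for traits with no genotypic signal). GCV and PCV are
100·sqrt(variance)/mean; H2 = sigma2_g/sigma2_p (broad sense — with
clonally propagated selections the entire genotypic variance is
heritable in practice). Genetic advance under truncation selection of
the upper proportion p uses k = phi(z_p)/p (k = 2.063 at p = 0.05,
checked against numerical integration of the truncated-normal mean).
Two GA conventions exist in the literature of this crop; the default is
the classical GA = k·sigma_p·H2 (= k·sigma2_g/sigma_p), with
`ga_formula="as_printed"` switching to k·sigma_g·H2. Category labels:
GCV/PCV low < 10%, moderate 10–20% (closed on both ends), high > 20%;
H2 low < 30%, moderate 30–60%, high > 60%.

## Trait associations

Correlations are product-moment on pairwise-complete adjusted means,
with p from t = r·sqrt((n−2)/(1−r²)) and codes *** / ** / * at
p ≤ 0.001 / 0.01 / 0.05. Regression works on z-scores (n−1 sd), so the
coefficients are standardized betas and the intercept is numerically
zero. Forward selection minimizes the Gaussian AIC
n·ln(RSS/n) + 2(p+1); a candidate tying the current AIC exactly is
still entered and flagged, and retention is by AIC only, never by the
per-term p-value. VIFs come from auxiliary regressions (equivalently the
diagonal of the inverse correlation matrix). Cross-validation uses
seeded random partitions (fresh permutation per repeat, numpy
Generator), reporting mean ± sd of RMSE, MAE and out-of-fold R² — folds
are deliberately hand-assigned so the seed alone fixes them.

## Structural-equation model

The pinned model has seven observed variables (LW, NL, PL, NPR, GPR,
NMR, TY) and four latents: VEG (marker LW) with free loadings for NL
and PL; first-order factors F_WPR (marker NPR) and F_WMR (marker NMR)
with GPR cross-loading on both; a second-order SINK (marker F_WPR) with
a free loading for F_WMR; structural paths VEG→SINK, SINK→TY, VEG→TY.
Free parameters: 8 coefficients + 11 variances (one per variable) = 19,
so df = 28 − 19 = 9.

Estimation minimizes the normal-theory discrepancy
F_ML = ln|Σ(θ)| − ln|S| + tr(S·Σ⁻¹) − p over the RAM parametrization
Σ = J(I−A)⁻¹Ψ(I−A)⁻ᵀJᵀ, with an analytic gradient, ten seeded starts
plus an independence start, L-BFGS-B followed by a trust-region Newton
polish (finite-difference Hessian of the analytic gradient) because the
likelihood surface of this family has flat ridges where first-order
methods stall. Convergence requires gradient max-norm < 1e-6; otherwise
an error reports the best F and gradient norm. chi2 = (n−1)·F_min,
GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²], SRMR is the root mean square of
the correlation-scale residuals over the lower triangle including the
diagonal. Standard errors come from the inverse observed information
(numerical Hessian of F scaled by (n−1)/2).

Numerical balance: the fit internally rescales S to correlation form and
maps the solution back. The model family is closed under diagonal
rescaling of the observed variables (every latent's scale is pinned by a
free-variance marker chain), so this is exact, and a test verifies
scale equivariance of chi2 and the standardized solution.

Variance parameters are deliberately unconstrained: negative (Heywood)
residual-variance estimates are permitted and flagged, because they are
an empirically documented symptom of this model family on real turmeric
data; a log-parameterization would hide them as boundary
non-convergence.

**Identification caveat.** Although df = 9 by counting, the sink
measurement block is locally under-identified: given the sink variance
and the F_WMR loading, the seven block parameters (two GPR
cross-loadings, two first-order disturbances, three indicator residuals)
face only six effective moment constraints, so they trade off along a
one-dimensional ridge at the optimum. The fit statistics, the implied
covariance, and the structural paths (including the standardized
VEG→SINK coefficient) are identified and recover truth in simulation;
the individual sink-block loadings and residuals are reported but their
standard errors are unreliable (near-singular information), consistent
with the identification warnings this model family is known to produce.
At small sample sizes a related boundary degeneracy (vegetative-factor
variance collapsing to zero with exploding loadings) can make the ML
problem have no interior optimum; the fitter then raises an explicit
convergence error rather than returning a spurious solution.

## Selection indices

Traits are min-max rescaled to 0–100 with 100 always the desirable pole
(direction-aware). The factor analysis is principal-component extraction
on the correlation matrix, retaining eigenvalues > 1 (if all eigenvalues
tie at exactly 1, one factor is kept with a warning), varimax rotation
by Kaiser's pairwise closed-form rotations (cross-checked against R's
`varimax` to ~1e-6 during development), and regression-method scores
Z·R⁻¹·L. The ideotype (100 on every rescaled trait) is projected through
the same score weights, never refit.

* **MGIDI**: Euclidean distance from the ideotype in factor-score space,
  ascending; per-factor contributions are squared-difference shares.
* **FAI**: proximity probability (1/d_ideotype)/((1/d_ideotype)+(1/d_anti))
  against the all-0 anti-ideotype, descending; d = 0 maps to exactly 1
  (or 0).
* **MTSI**: for two environments the stability input is the negated
  absolute between-year difference, rescaled (100 = perfectly stable),
  blended as theta·performance + (1−theta)·stability with theta = 0.5 by
  default; theta = 1 reduces MTSI to MGIDI on pooled means exactly.
  This is a deliberate two-environment substitute for multi-environment
  stability machinery, which needs more than two environments.
* **Smith–Hazel**: b = P⁻¹Gw on entry-mean covariances, with the
  genotypic covariance from the mean-cross-product analogue of the
  variance-component decomposition; economic weights default to 1 per
  standardized trait and are a logged configuration item; a singular P
  is ridge-regularized (lambda = 1e-8·trace) with a warning.

Selected-set size is round-half-up of SI·n (20% of 265 → 53); index ties
break lexicographically by genotype label, deterministically. Selection
gains discount the selected-vs-population differential by per-trait H²
(as a proportion) and report it as a percentage of the population mean.
Coincidence counts pairwise common selections as a percentage of the
selected-set size (the pair minimum if sizes differ, with a warning),
plus the all-methods intersection and full Venn partition counts.

## Synthetic trials

The generator mirrors the biology the pipeline targets: a standardized
latent vegetative vigor VEG per genotype (between-family share 0.25,
emulating maternal half-sib families under open pollination), sink
strength SINK = 0.86·VEG + disturbance, and per-trait genotypic values
mu + sqrt(sigma2_g)·(lv·VEG + ls·SINK + lu·U) with the unique share lu²
filling the remainder, so configured genotypic variances are exact and
genetic correlations follow the latent network (dry recovery loads
negatively on SINK, creating the yield–quality trade-off). Plot values
add a fixed year offset, genotype-by-year noise (default 10% of
sigma2_g), a small block effect (10% of plot error, reflecting the
generally non-significant block effects of a well-run augmented design)
and plot error set from per-trait target heritabilities. Default means,
variances and H² are calibrated to magnitudes typical of a two-year
turmeric half-sib trial (e.g. total yield mean 0.5 kg/plant, H² ≈ 0.8;
dry recovery mean 22.4%, H² ≈ 0.96).

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: spatial autocorrelation
within beds, paternal identity (paternal variance is folded into the
within-family deviation), non-normal trait distributions, outliers and
designed missingness, and measurement error correlated across traits
beyond the latent structure. The generator's observed-trait structure is
also deliberately close to (but not identical with) the SEM, so SEM
recovery tests are meaningful rather than circular: vegetative traits
carry no direct sink loadings, and sink traits no direct vegetative
loadings, while the fitted SEM must still cope with adjusted-mean error.

## Problem sizes and numerical choices

The test suite runs the full study at its native size (260 test
progenies, 14 blocks, 2 years) where a single analysis is exercised, and
scales Monte-Carlo studies to what the estimators need: 100 single-year
trials of 300 progenies for H² recovery (tolerance ±0.07 on the mean),
50 datasets of n = 265 for standardized-path recovery (±0.1 around
0.86), 150–400 replicates for the type-I calibration of the SEM χ² and
Bartlett tests (binomial 95% bounds around 0.05), and 100 replicates for
the selection-response check (≥95 successes). Optimizer tolerances:
L-BFGS-B ftol 1e-14/gtol 1e-10, polish gtol 1e-9, convergence
declared at gradient max-norm < 1e-6; covariance matrices are declared
non-PD by Cholesky failure and penalized with a large objective value.
All randomness flows from explicit integer seeds through
numpy Generators; the pipeline derives per-stage seeds from the global
seed by a stable CRC-based hash so toggling stages never shifts another
stage's stream.

## Known limitations

* Block adjustment is check-based only; no spatial row–column or mixed
  model (BLUP) alternative, so precision is bounded by check replication.
* G×E and error are confounded at the adjusted-means level; with two
  years the interaction cannot be separated from measurement noise.
* The SEM is a single fixed family (no general model language, no robust
  estimators, no missing-data FIML — the pipeline feeds complete-case
  covariances of adjusted means, which have no designed missingness).
* Smith–Hazel weights are a modelling choice, not data; results are
  reported for the logged weight vector only.
* The pooled-ANOVA heritability is an entry-mean quantity; comparisons
  with per-plot heritabilities from other designs need care.
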