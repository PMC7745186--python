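# Methods

This note documents the statistical models implemented in `mrsum`, the
defaults and numerical choices, what the synthetic-data generator does and
does not emulate, and known limitations.

## Data model

For J genetic variants, the observed summarized data are per-variant
association estimates with a risk factor, `bx_j` with standard error
`bxse_j`, and with an outcome, `by_j` with standard error `byse_j`.  All
estimates are assumed pre-harmonized to common effect alleles and, for the
two-sample setting, to come from non-overlapping samples.  Under the
instrumental-variable assumptions, `by_j ≈ θ bx_j` for valid instruments,
with θ the causal effect of the risk factor on the outcome (in outcome
units per unit of the risk factor; log odds ratios if `by` are from
logistic regressions).

When variants are correlated (linkage disequilibrium), a J×J correlation
matrix ρ must be supplied, aligned and allele-harmonized to the
associations; the covariance of the outcome associations is then taken as
`Ω_ij = byse_i byse_j ρ_ij`, i.e. the correlations between association
estimates are assumed to equal the variant correlations.
`flip_correlation` re-orients rows/columns of an LD matrix computed with
effect and reference alleles swapped for some variants (diagonal kept at
+1; the operation is an involution).

## Univariable estimators

**IVW.**  Weighted regression of `by` on `bx` through the origin with
weights `byse⁻²`; with a correlation matrix, generalized least squares with
Ω.  `model="fixed"` uses the weighted-regression SE with unit residual
variance; `model="random"` multiplies it by `max(1, sqrt(Q/(J−1)))`
(multiplicative random effects), where Q is Cochran's heterogeneity
statistic `Σ w_j (by_j − θ̂ bx_j)²`.  The default is fixed for J ≤ 3 and
random otherwise — the switch point is implementation-defined, chosen so
that dispersion is only estimated when there are enough residual degrees of
freedom.  `robust=True` replaces the fit by Tukey-bisquare
(c = 4.685) iteratively reweighted least squares, initialized from a
median-regression fit with MAD residual scale (an MM-flavoured scheme;
statsmodels provides the M-estimation machinery).  `penalized=True`
multiplies each weight by `min(1, 20 p_j)` where `p_j` is the upper-χ²₁
tail probability of the variant's heterogeneity contribution at the plain
IVW estimate; the constant 20 leaves variants untouched unless their
contribution is clearly outlying and is recorded in the result's `extra`.

**MR-Egger.**  Same regression with an intercept, after flipping each
variant's `(bx, by)` pair so `bx ≥ 0` (the fit is otherwise not invariant
to arbitrary allele orientation).  The slope estimates θ under the InSIDE
assumption; the intercept estimates the average direct (pleiotropic)
effect.  SEs always carry the multiplicative dispersion
`max(1, sqrt(Q_R/(J−2)))` with Rücker's Q.

**Median.**  Simple: median of ratio estimates.  Weighted: the 50% point
of the weight-cumulative distribution of sorted ratio estimates with
linear interpolation, weights `bx_j²/byse_j²` (the inverse first-order
ratio variance); with equal weights this equals the simple median.  Penalized: the weighted variant with weights further multiplied by
`min(1, 20 p_j)`, the penalty evaluated about the IVW estimate (penalizing
about the weighted median itself would spare a heavily-weighted outlier).
The SE is the SD of the estimate over parametric-bootstrap resamples
`bx* ~ N(bx, bxse)`, `by* ~ N(by, byse)` (default 10 000), with the weights
held fixed across resamples as in the original estimator.  A seed is
required; results are bit-reproducible given one.

**Maximum likelihood.**  `bx_j ~ N(ξ_j, bxse_j²)`,
`by_j ~ N(θ ξ_j, byse_j²)`; the nuisance true effects ξ profile out in
closed form, the 1-D profile likelihood is maximized by Brent search
started at the fixed-effect IVW estimate, and the SE comes from the
numerical curvature at the maximum.  With a correlation matrix the same
profile is computed with dense covariance solves.

**Mode-based estimate.**  The mode (dense-grid argmax, 2001 points
spanning the ratios ± 3 bandwidths) of a normal-kernel density of the
ratio estimates; kernel weights equal (`weighting="simple"`) or inverse
ratio-variance (`"weighted"`), with first-order (`stderror="simple"`) or
second-order (`"delta"`) ratio SEs.  Bandwidth
`h = φ · 0.9 · min(SD, MAD/0.6745) · J^(−1/5)` (modified Silverman rule),
φ defaulting to 1.  A grid, not a derivative, locates the mode because the
density is often multimodal.  SE by parametric bootstrap (501-point grid
per replicate).  If all ratios coincide the estimate short-circuits to the
common value.

**Heterogeneity-penalized model averaging.**  Every subset S of ≥ 2
variants contributes a normal component centred at the subset IVW estimate
of the ratio estimates (first-order weights on second-order SEs) with the
subset IVW SE, weighted by `prior^|S| (1−prior)^(J−|S|) exp(−Q_S/2)`.
The averaged distribution is evaluated on a grid (default: ratios ± 5 max
SE, step 0.001 × range); the confidence set is the smallest
(highest-density) set of grid points holding 1−α of the normalized mass and
may be several disjoint intervals — the reported `ci_lower/ci_upper` are
the hull and `extra["ci_intervals"]` the list.  The reported `std_error`
is the mixture SD and the p-value the two-sided mixture tail mass at 0;
both are summaries of the averaged distribution rather than Wald
quantities.  Enumeration is 2^J (vectorized over bitmasks), capped at
J = 20; components covering all but 1e-12 of the weight are kept for the
grid evaluation.  A warning is raised if ≥ α/2 mass sits at a grid edge.

**Contamination mixture.**  Each ratio estimate is either valid,
`N(θ, se_j²)`, or invalid, `N(0, se_j² + ψ²)` with ψ the SD of invalid
estimands (`psi=0` selects 1.5 × SD of the ratio estimates).  The profile
log-likelihood over the θ grid takes the better classification per variant
(ties to valid); the estimate is the grid argmax, the confidence set the
likelihood-ratio region against χ²₁ (possibly disjoint), the p-value the
likelihood-ratio test of θ = 0, and `valid_variants` the classification at
the maximum.  The reported `std_error` is the equivalent-width of the
interval containing the estimate.

**Lasso.**  Minimize `Σ_j w_j (by_j − α_j − θ bx_j)² + λ Σ_j |α_j|`
(`w_j = byse_j⁻²`) by exact coordinate descent (soft-thresholding each
α_j, closed-form θ update).  Variants with `α̂_j = 0` form the valid set;
the reported estimate is the IVW fit on that set.  `lambda=0` picks λ by a
heterogeneity stopping rule: descend 100 log-spaced values from the
smallest λ retaining every variant (spanning three decades) and stop at
the first whose valid set S satisfies `Q_S ≤ χ²_{0.95}(|S|−1)`; if the
data fit perfectly the full set is returned at λ = 0.  Fewer than 2
retained variants is an error suggesting a larger λ.

**Heterogeneity.**  Cochran's Q about the fixed-effect IVW fit (J−1 df) or
Rücker's Q about the Egger fit (J−2 df), with upper-χ² p-values.

**run_all** executes a token-selected panel (default all eight univariable
tokens) with default options, skipping methods whose preconditions fail.
Robust/penalized IVW variants are not part of the default panel; call
`ivw` with flags for those.

## Multivariable estimators

`mvivw` regresses `by` on the J×K matrix of risk-factor associations
(no intercept, weights `byse⁻²`, GLS with Ω when requested); heterogeneity
has J−K df and the default model is fixed for J ≤ K+2, random otherwise
(the K = 1 case then coincides exactly with univariable IVW).  A risk
factor whose associations are all exactly zero is undetermined: it is
dropped from the fit and reported NaN, leaving the other coefficients
unchanged; genuine collinearity raises an error naming the dependent
columns.  `mvegger` adds an intercept after sign-flipping each variant's
row so the `orientate`-th (default first) risk-factor association is
non-negative; the orientation choice is recorded in the output.
`mvmedian` minimizes `Σ_j w_j |by_j − Σ_k θ_k bx_jk|` — weighted L1
(median) regression, solved exactly as a linear program (HiGHS) — with
parametric-bootstrap SEs; the L1 formulation was chosen because no
algorithm is canonical for the multivariable median and the LP solution is
deterministic and exact.  `mvlasso` extends the univariable lasso with a
θ vector (valid set must exceed K variants; Q on |S|−K df).
`predicted_outcome_associations` returns fitted values `x_jᵀθ̂` with
variance `x_jᵀ Cov(θ̂) x_j` only — uncertainty in the coefficients, not in
the risk-factor associations, which are treated as known.

## Visualizations

Each plot function computes a `PlotTable` (rows of label, x/y points and
bounds, a `kind` tag; metadata with axis labels and reference lines) and
renders the figure from the table alone, so a saved table regenerates the
identical figure.  Scatter (univariable: associations with the fitted
line; multivariable: predicted vs observed outcome associations with the
gradient-1 diagonal), forest (ratio estimates and/or method estimates;
default variant rows + IVW), funnel (ratio estimate vs precision 1/SE with
the IVW reference line), and leave-one-out (IVW omitting each variant,
plus the full-data reference row).  Variant rows use first-order ratio SEs
with normal quantiles by default (`second_order=True` switches); row order
follows the input, optionally sorted by estimate.  Output is static
(PNG/SVG/PDF by extension).

## Synthetic data generator

`SimScenario` emulates the regime of a typical two-sample analysis of tens
of independent variants (defaults: J = 28, instrument effects
|N(0.3, 0.1)|, association SEs ≈ 0.05 with ±20% jitter, true effect 0.5).
Instrument effects are folded positive by default to avoid the bx ≈ 0
weak-instrument pathology in ratio-based tests (`signed_bx=True` disables
this for orientation-invariance checks).  Direct (pleiotropic) effects are
assigned to a `prop_invalid` fraction of variants: balanced `N(0, σ)`,
directional `|N(0, σ)|`, or InSIDE-violating (correlated with instrument
strength).  Outcome associations are drawn
`by_j ~ N(θ bx_j + α_j, byse_j)`, optionally with exchangeable
cross-variant correlation (the matrix is then attached to the dataset).

The realized `bx_j` plays the role of the true instrument effect and the
reported associations carry no additional measurement error, so moment
estimators are exactly unbiased under no pleiotropy and CI coverage checks
are clean.  Real summarized data differ in ways the generator does not
model: genuine sampling error in `bx` (regression dilution and weak
instruments), winner's curse from variant selection, sample overlap,
allele-harmonization errors, and realistic LD structure.  Passing tests
therefore validate the estimators under their stated models, not
robustness to those artefacts.

`benchmark` runs a method panel over replicate datasets (independent
seed streams spawned from the scenario seed) and reports mean estimate,
empirical SD, mean SE, bias, RMSE, CI coverage and the rejection rate of
θ = 0.  Bootstrap-based methods use a moderate default of 1000 bootstrap
iterations inside benchmarks (repeated per replicate); single analyses
default to 10 000.

## Numerical choices and degenerate inputs

- CIs are two-sided at level 1−α (default α = 0.05), normal quantiles by
  default, Student-t on request with the fit's residual df.
- p-values are two-sided against θ = 0 throughout.
- Variants with `bx = 0` are flagged in the ratio table (NaN, `defined`
  False) and dropped from plots with a warning; regression-based methods
  remain defined and unaffected.
- Correlation matrices are validated (symmetry 1e-8, unit diagonal,
  entries in [−1, 1]) but not forced positive-definite; GLS adds a 1e-8
  ridge with a logged warning if the Cholesky factorization fails.
- Non-finite inputs are rejected at construction rather than silently
  dropped.
- All-identical ratio estimates short-circuit the KDE/profile methods to
  the common value.
- Coordinate descent for the lasso methods iterates to 1e-12 with exact
  soft-thresholding, so retained variants have exactly zero intercepts.
- Grids (hetpen, conmix) default to [min ratio − 5·max SE,
  max ratio + 5·max SE] with step 0.001 × range; CIs are resolved to the
  grid step.
- Every stochastic routine takes an explicit seed (`numpy` Generator) and
  is bit-reproducible; replicate streams use `SeedSequence.spawn`.

## Problem sizes used in the checks

The test-suite simulations use J = 20–50 variants with 500–1000
replicates, and bootstrap sizes of a few hundred inside replicated runs —
sizes chosen to keep Monte-Carlo error well inside the tested bands while
the whole suite runs in well under a minute of simulation time.

## Limitations

- No effect-allele harmonization, LD estimation, instrument selection, or
  sample-overlap / winner's-curse corrections: inputs are taken at face
  value.
- `hetpen` is exponential in J (capped at 20 variants); use `conmix` for
  larger panels.
- The robust (Tukey bisquare) fits are M-estimates with a high-breakdown
  start rather than a full MM-estimator.
- Multi-interval confidence sets are summarized by their hull in the
  scalar fields; consumers needing the disjoint pieces must read
  `extra["ci_intervals"]`.
- `mvlasso` and the univariable lasso do not support correlated variants.
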