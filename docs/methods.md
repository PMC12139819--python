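# Methods

## The model

`zigrow` models annual growth increment and survival of clonally replicated
tree genotypes planted across common gardens that span a winter-temperature
gradient, summarized by MCMT (mean coldest month temperature, degC). Growth
and mortality are treated as two parts of one zero-inflated Gaussian mixed
model. Dead trees are coded as growth 0, so zeros are a mixture of
"structural" zeros (mortality) and "sampling" zeros (live trees with no
measurable growth).

For observation *i* (one individual in one year), with
`y_i = log(growth_i + 1)`:

* conditional part: `y_i ~ Normal(mu_i, sigma^2)` with
  `mu_i = x_i' beta_c + z_i' b_c`
* zero-inflation part: `p_i = logistic(x_i' beta_z + z_i' b_z)`
* density: `f(0) = p + (1 - p) * phi(0; mu, sigma^2)` and
  `f(y) = (1 - p) * phi(y; mu, sigma^2)` for `y > 0`.

The zero-inflation mixes a point mass with the Gaussian *density value* at
zero. This is the numerical convention of glmmTMB's continuous
zero-inflation, and the engine's log-likelihood agrees with glmmTMB to
numerical precision on shared test fixtures.

The fixed-effect design is identical in both parts: garden MCMT (g), home
MCMT (h), their squares, all pairwise products of these four, genomic PC
scores 1-3, and PC x g, PC x g^2 interactions — 18 named columns
(`intercept, g, h, g2, h2, g:h, g2:h2, g2:h, g:h2, pc1..pc3, pc1:g..pc3:g,
pc1:g2..pc3:g2`). A `genetics_only` variant drops every column containing
h (12 columns); a `climate_only` variant drops every PC column (9 columns).
Both parts carry independent random intercepts for genotype, garden, block
nested in garden, year, and individual.

### Covariate scaling

Numeric covariates are scaled without centering: each variable is divided
by `sqrt(sum(x^2) / (n - 1))`, the non-centered convention of R's `scale`.
Squares are computed *after* scaling and are not rescaled again; this is
the simplest self-consistent reading, and the recorded divisors make every
prediction expressible in raw degC. Divisors are computed once on the
training observations and reused for held-out or new data, so
cross-validation folds leak no information through the scaling.

## Estimation

The marginal likelihood integrates the stacked random intercepts `b` out of
the joint likelihood. We use the Laplace approximation

`L(theta) = l(theta, b_hat) + dim(b)/2 * log(2*pi) - 1/2 * log det H`,

where `b_hat` maximizes the joint log-likelihood (damped Newton iterations;
gradient infinity-norm below 1e-8) and `H` is the negative Hessian at the
mode. `H` has the form `A' W A + D` with one indicator per grouping factor
and part; the solver eliminates the largest factor (individuals), whose
block is 2x2-block-diagonal because two individuals never share an
observation row, and forms a dense Schur complement over the remaining
~200 coefficients. This makes each Newton step a few vectorized bincounts,
small sparse products, and one 200-dimensional Cholesky.

The outer optimizer (L-BFGS-B, at most 200 iterations) works on
`(beta_c, beta_z, log sigma, log re-SDs)` with the *exact* gradient of the
Laplace objective, including the dependence of `b_hat` and `log det H` on
the parameters; this requires third derivatives of the observation
log-density, which are implemented analytically and verified against
finite differences. Fixed effects are optimized in a QR-orthonormalized
column space (the polynomial interaction columns are severely collinear
under non-centered scaling) and mapped back through the triangular factor.
The outer tolerance is 1e-5 on the per-observation-scaled objective.

Initialization is deterministic: OLS on the positive responses, a
ridge-stabilized logistic regression on the zero indicator, `sigma` from
the OLS residual SD, and all random-intercept SDs at 0.5.

The covariance of the fixed effects is the corresponding block of the
inverse observed information of the Laplace objective (one-sided finite
differences of the analytic gradient, symmetrized). Variance parameters
that end at their box bounds are not interior stationary points and are
excluded from the information matrix; a residual negative eigenvalue from
differencing noise is repaired by nearest-PSD projection and flagged on
the fit. Per-coefficient Wald chi-square tests use df = 1; every model
term contributes exactly one column. A joint multi-column Wald test is
available for grouped hypotheses.

Random-intercept SDs below 1e-3 are flagged as boundary estimates, not
errors; the individual-level intercept is retained even though it is
weakly identified for individuals observed once (it is confounded with
sigma there).

### Oracles

Two independent likelihood oracles guard the engine:

* a closed-form multivariate-normal marginal likelihood for
  conditional-only (Gaussian) instances — the Laplace approximation is
  exact there and the tests require agreement to 1e-6;
* dense adaptive Gauss-Hermite quadrature (>= 50 nodes per dimension,
  mode-centered and curvature-scaled per independent random-effect
  component) for small mixed zero/positive instances.

On instances with moderate zero-inflation random-effect SDs the Laplace
log-likelihood is within ~1e-3 of the quadrature value; the discrepancy
grows with the zi-part SD and shrinks with observations per group, as
expected for Laplace on Bernoulli-like contributions. glmmTMB serves as an
additional independent cross-check in one test.

## Predictions, reaction norms, fitness proxy

Predictions report three quantities: the conditional growth prediction,
the mortality probability, and the overall fitness proxy
`(1 - p) * growth`. Growth is back-transformed with `exp(eta) - 1` by
default; a lognormal-mean correction `exp(eta + sigma^2/2) - 1` is
selectable. Correlation-based evaluation defaults to the log scale, which
is invariant to that choice.

Reaction norms evaluate one genotype (its own home MCMT and PC scores) on
an evenly spaced MCMT grid — by default 100 points from -23.9 to 9.8 degC,
covering both home-climate normals and garden-year climates — with all
random effects at zero (population-level prediction). Unknown random-effect
levels always predict zero deviation; predictions for a new garden or
genotype are fixed-effects-only. Optimum temperatures are grid argmaxes;
ties break toward the colder temperature for determinism. The transfer
distance view re-indexes the same curve by garden minus home MCMT.

## Cross-validation and variant comparison

Leave-one-garden-out cross-validation refits the model per fold on the
remaining gardens (scaling recomputed per fold) and predicts the held-out
garden. A single fold fit serves all years of the held-out garden.
Prediction ability is Pearson's r per garden x year, reported two ways:
conditional (observed zeros excluded) and overall (dead trees as observed
zero, predictions multiplied by survival probability). An undefined
correlation (constant vector after exclusion) is reported as missing,
never as 0.

Variants are compared by a paired two-sided exact Wilcoxon signed-rank
test over shared (garden, year) fold scores; zero differences are dropped
and counted (exact-conditional convention). A paired t-test is available
by configuration. The Wilcoxon default is a deliberate choice for ~30
paired, non-normal fold scores.

## Rangewide projection

For each raster cell with MCMT inside the mask bounds, the overall fitness
proxy of every genotype is evaluated at that cell's temperature (fixed
effects only) and the argmax genotype's ancestry proportion q is mapped.
Cell values are quantized to 0.01 degC *before* prediction, so the
unique-value lookup is exact, and argmax ties break toward the lowest
genotype index. Mask bounds default to the training gardens' MCMT range
(-16.5 to 9.8 degC) and are configurable. Historic and future maps are
compared cellwise over cells unmasked in both; the headline summary is the
fraction of comparable cells whose best genotype changes.

Raster I/O covers ESRI ASCII grids (parsed directly) and single-band
GeoTIFFs through `tifffile`'s pixel-scale/tiepoint/nodata tags. CRS
handling is a string passthrough; reprojection is out of scope.

## The synthetic trial generator

No public accession provides the trial data the pipeline targets, so the
generator is a first-class, tested module that emulates the study
conditions:

* 45 clonal genotypes whose ancestry proportion q (share of the
  warm-adapted species at K = 2) is drawn from a mixture of near-0,
  near-1, and uniform intermediate components;
* home MCMT increasing with q over [-23.9, -3.8] degC (noise SD 2.5 degC,
  clipped);
* PC1 built as minus standardized home MCMT plus noise whose scale is
  solved (Brent) so the realized correlation equals the target -0.69
  exactly; a target of exactly +-1 selects the noise-free affine limit.
  PC2 and PC3 carry weak home-climate loadings (realized |r| < 0.3 by
  construction, via orthonormalized noise);
* 17 gardens on an even MCMT grid over [-16.5, 9.8] degC (anchor gardens
  at both extremes), with a shared year shift (SD 0.8 degC) and
  garden-by-year jitter (SD 0.4 degC); 2 blocks; one individual per
  genotype x garden x block observed in 2 years (~3060 observations);
* true fixed effects specified in the scaled design-column space (the
  table below), with a quadratic growth response whose optimum shifts
  warmer with warm-species ancestry and U-shaped mortality that is
  steeper at the cold end; the `pc2:g2` coefficient is exactly zero and
  serves as the truly null genotype-by-environment curvature term in
  type-I-error experiments;
* random-intercept draws for all five factors in both parts;
* structural zeros drawn per observation from the zi part; a structural
  zero sets growth 0 and survived = false. Positive growth is
  `exp(eta + eps) - 1` with a truncation re-draw below zero, so live trees
  have strictly positive growth by default (`include_sampling_zeros`
  switches to clipping, producing live zeros for mixture stress tests).

Non-default numeric choices and why:

| quantity | default | rationale |
| --- | --- | --- |
| conditional `intercept, g, g2` | 4.8, 0.50, -0.55 | peak growth ~135 cm near mildly warm gardens, ~4 cm for surviving trees at the coldest garden; the intercept keeps live log-growth well above zero everywhere, so the truncation re-draw essentially never binds and structural zeros are not confounded with the Gaussian mass near zero |
| conditional `pc1, pc1:g` | -0.25, -0.12 | warm-species ancestry raises growth and shifts the optimum warmer |
| zi `g, g2` (pre-calibration intercept -1.8) | -0.35, 0.9 | mortality concentrated at both extremes, worse at the cold end |
| conditional RE SDs | 0.30/0.20/0.15/0.15/0.30 (genotype/garden/block/year/individual) | log-scale heterogeneity of a multi-site trial; no empirical magnitudes are available, so these are explicit assumptions. The garden SD is at the low end of the plausible range because it propagates directly into the sampling noise of the garden-climate coefficients (only 17 gardens), and recovery experiments must be able to resolve small biases |
| zi RE SDs | 0.15/0.15/0.10/0.05/0.15 | mortality heterogeneity assumed weaker than growth heterogeneity |
| residual sigma | 0.5 | log-scale year-to-year measurement scatter |

The zero-inflation intercept is calibrated per realization: after drawing
covariates and random effects, a Brent solve shifts the intercept so the
mean structural-zero probability equals the 27% target, and the shifted
intercept is recorded as the true value. This removes super-binomial
variation in the realized zero fraction (only indicator-draw noise
remains, SE ~0.008 at ~3060 observations). The cost is that the true zi
intercept is weakly correlated with the realized garden/year random
effects, which makes its Wald coverage slightly conservative-to-liberal in
recovery experiments; all other coefficients are unaffected.

What the generator deliberately does not emulate: mortality persistence
across years (each observation draws its structural zero independently),
herbivory and measurement-error artifacts (negative increments, missing
values) beyond what QC tests construct directly, spatial structure within
gardens, linkage-disequilibrium-realistic SNP matrices, and multivariate
climate. Passing tests therefore demonstrate correctness of the machinery
under the stated generating model, not robustness to these real-data
features.

The truncation re-draw makes live growth a truncated lognormal while the
fitted conditional part assumes an untruncated Gaussian on the log scale;
with the default effect sizes the truncation probability is negligible
except in the most extreme cells, and recovery experiments show no
material bias from it.

## Numerical choices and degenerate inputs

* Inner Newton: damping added when the joint Hessian is not positive
  definite (possible on zero rows far from the mode); step halving on the
  joint objective.
* No zero responses: the zi intercept would diverge; the conditional model
  is fitted and the zi part pinned at p = 0 (intercept -30), with a
  warning. All-zero responses: degenerate fit returned with a warning,
  `converged = False`, sigma not estimable.
* Singular fixed-effect designs raise a rank-deficiency error naming the
  collinear columns (QR with pivoting).
* Quality control order: excluded genotypes/years, negative growth
  removed, live missing-growth rows dropped, dead rows set to growth 0
  (including dead rows with missing growth — the structural-zero coding).
  QC is idempotent and row-conserving; duplicate (individual, year) rows
  are an error, not a silent dedup.
* Growth of exactly 0 on a live tree is retained as a sampling zero; the
  mixture likelihood handles it.

## Problem sizes used by the test suite and acceptance script

Simulation-heavy checks run at explicitly chosen scales: parameter
recovery uses 60 replicates of the full default design (~3060
observations each); the type-I-error experiment uses 200 replicates of a
reduced design (20 genotypes x 10 gardens, ~800 observations — the
smallest scale at which observed-information SEs match the empirical
sampling spread of interaction terms); oracle comparisons use 20-600
observations with at most 6 random-effect levels.
These sizes give each check clear statistical power while keeping the
whole suite runnable on a laptop in minutes.

## Known limitations

* The Laplace approximation is least accurate for the zi part when groups
  are small or zi RE SDs large; there is no adaptive-quadrature fallback
  in the fitting path (the quadrature code is an oracle only).
* No REML, no random slopes, no cross-part random-effect correlations, no
  dispersion formulas.
* Prediction intervals and posterior simulation of random effects are out
  of scope; only point predictions and Wald inference on fixed effects are
  provided.
* The paired variant comparison treats fold scores as exchangeable pairs;
  spatial or temporal correlation between folds is ignored.
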