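# Methods

## Model

`survgam` fits a two-part ("delta" or hurdle) model to tow-level trawl
catches: occurrence `Z ~ Bernoulli(pi)` with a logit link, and positive
biomass `Y | Z=1 ~ Gamma(mu, phi)` with a log link, parameterized so that
`Var(Y) = mu^2 / phi`. Both linear predictors contain an intercept, year
fixed effects (treatment coding, first year as reference — predictions are
invariant to this choice), P-spline smoothers of bottom temperature and
log depth, latent spatial/spatio-temporal fields, and the log swept area
as an offset. The offset enters both sub-models' predictors, including the
logit-scale one; an offset on the logit scale is an unusual modelling
choice, but it is the literal reading of "effort enters all the models",
and with the narrow swept-area spread of a standardized survey its effect
is small. Expected density is `pi * mu`.

The two sub-models are independent given the data split (zeros versus
strictly positive tows; zeros never enter the Gamma likelihood), so they
are fitted separately and their degrees of freedom and marginal negative
log-likelihoods add.

## Smoothers

Classic P-splines: cubic B-splines on equally spaced knots spanning the
observed covariate range (extended, unclamped), with a second-order
difference penalty. Uniform knots make the penalty null space correspond
exactly to {constant, linear}, so the basis is reparameterized into an
unpenalized linear column (the constant is absorbed by the intercept) plus
penalized columns whose coefficients are iid Gaussian; the smoothing
variance of each smoother is a hyperparameter (the mixed-model view of
penalized smoothing). Default: 8 knots per smoother (6 in the scaled test
experiments). Covariate values beyond the observed range are clamped at
the boundary for prediction and the affected cells flagged as
extrapolated.

## Latent fields

Spatial dependence uses the SPDE construction of a Matern (nu = 1) field:
P1 finite elements (mass-lumped C, stiffness G) on a Delaunay mesh over
greedily thinned tow locations (first-seen point kept, later points within
the cutoff dropped) plus a boundary ring sampled from the convex hull
buffered outward — by default three mesh cutoffs, on the order of the
spatial range — to limit boundary variance inflation. The precision is
`Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G)` with
`kappa = sqrt(8)/range` and `tau` set so the stationary marginal SD equals
`sigma`; "range" is therefore the distance at which correlation falls to
roughly 0.13. Spatio-temporal structures are Kronecker products with an
AR1 (stationary scaling, so the marginal variance is constant across
years), iid, or random-walk temporal precision; the random walk anchors
the first year at the stationary spatial distribution to keep the density
proper. Fields are evaluated at tow and grid locations through
row-stochastic barycentric weights.

## Estimation

Maximum marginal likelihood with a Laplace approximation over the latent
vector (penalized spline coefficients, spatial field, spatio-temporal
field): an inner sparse Newton iteration finds the latent mode (symmetric
sparse LU factorizations; inner gradient tolerance 1e-8), and the marginal
negative log-likelihood is the joint at the mode plus half the
log-determinant of the inner Hessian. The outer optimization (L-BFGS-B,
forward-difference gradients, projected-gradient tolerance 1e-3) works on
log/atanh-transformed hyperparameters only: the fixed effects are profiled
inside the inner Newton (they carry no prior and the Laplace
log-determinant is taken over the latent block alone, via the Schur
identity `logdet H_uu = logdet J + logdet (J^-1)_bb`). Profiling agrees
with the non-profiled marginal up to the weak dependence of the latent
log-determinant on the fixed effects, and is exact for Gaussian responses
— the test suite verifies the Laplace value against the closed-form
Gaussian marginal to at least eight digits, and the profiled optimum
against the closed-form GLS solution.

Standard errors: fixed effects from the joint Gaussian approximation at
the mode (sparse precision over fixed + latent effects, also used for
posterior draws); hyperparameters from a central finite-difference Hessian
of the profiled marginal on the working scale, with Wald intervals
transformed to the natural scale. Degrees of freedom count outer
parameters only — fixed effects plus hyperparameters, never latent
effects. With 24 survey years this bookkeeping yields the familiar df
ladder (49 for a year-only model up to 65 for the full AR1 structure),
which the tests assert.

Degenerate inputs: constant covariates, collinear mesh points, zero-area
triangles, non-positive hyperparameters, and fits with fewer than 10
positive tows are rejected with specific errors; all-zero year-effect
columns (a year absent from the positive subset) are dropped with a
warning and treated as reference-level in prediction.

## Model selection and validation

Covariate screening computes both Pearson and Spearman correlations and
screens on the larger magnitude (|R| < 0.6), plus variance inflation
factors (VIF < 3; exact collinearity is reported as an infinite sentinel,
not an exception). Candidate structures are compared by AIC
(`2 nll + 2 df`) and Akaike weights; the comparison table reports
`delta_aic = AIC_best - AIC_m` (best = 0, worse negative) and, when
cross-validation is run, `delta_elpd = ELPD_m - ELPD_best` on the same
convention. k-fold cross-validation (k = 4 by default) randomly partitions
tows into near-equal folds; each fold is scored by its held-out log
predictive density under the delta model at plug-in estimates —
`log(1 - pi)` for zeros, `log pi` plus the Gamma log-density for positives
— with latent fields at their predictive means given the training fit
(zero for sub-spaces the training data do not inform). ELPD is reported as
a sum over held-out tows. Residual checks use randomized quantile
residuals (uniform randomization on the zero mass, Gamma CDF above it) and
a Moran's-I-style k-nearest-neighbour statistic against spatial structure.

## Derived products

Prediction uses `log(reference swept area)` as offset, so gridded
densities are kg per reference swept-area unit; cell biomass is
`density x cell area / reference area`, and the yearly index is the cell
sum in tonnes, multiplied by a fixed catchability factor as the literal
final operation (snow-crab preset 0.126; default 1). The reference swept
area defaults to the generator's mean tow swept area (0.025 km^2).
Interval bounds are 2.5/97.5 percentiles over seeded draws from the joint
Gaussian approximation of each sub-model propagated through the
prediction (500 draws by default; non-finite draws are rejected, with
failure if more than 10% reject). Centre of gravity is the
biomass-weighted mean of cell coordinates with a weighted per-axis
variance as dispersion; it can also be computed directly from tow data
with tow biomasses as weights. The design-based comparator is the
stratified mean catch per swept area expanded by stratum areas; strata
without tows are omitted with a warning, which is exactly how coverage
gaps bias it. Index agreement is the squared Pearson correlation over
shared years; the divisional fishing check is an ordinary least-squares
regression of yearly biomass on yearly catch, fitted per division.

## Synthetic data: what it emulates, and what it does not

The generator mimics a spring multispecies bottom-trawl survey on a
virtual shelf bank. Defaults: 300 x 300 km domain, 5-km truth grid, 10
years, 150 stratified-random tows per year allocated to depth-quantile
strata proportionally to area; swept areas lognormal around 0.025 km^2
(CV 8%, the survey's tow-to-tow spread is not published, so a narrow
lognormal is assumed); occupancy around one half (zero-inflated biomass).
Bathymetry is a smooth cross-bank gradient with bumps plus fine-scale
ridges, and bottom temperature a large-scale gradient plus mesoscale
fronts, a yearly anomaly, and an optional warming trend. The
sub-range-scale structure in both covariates is deliberate: a covariate
that varies only at the scale of the latent field is unidentifiable from
it (spatial confounding), and real bathymetry and bottom temperature do
vary below the field's correlation range. Covariate responses are
quadratic domes on the link scale — preferred temperature 3 degrees C and
preferred depth 80 m by default — so the true optima are known
analytically. Latent fields are drawn from the exact SPDE GMRF used in
fitting, on a 12-km truth mesh (20 km in the recovery experiments, where
the fitting mesh is 25 km), with defaults range 70 km, spatial SD 0.8,
spatio-temporal SD 0.5 and AR1 rho 0.7. Occurrence is simulated as
Bernoulli(pi) without a swept-area adjustment, while the fitted model
includes the logit-scale offset; with the narrow swept-area distribution
the mismatch is negligible but it is a real (documented) difference.

Not emulated: vessel or gear changes, seasonal migration, size/sex
structure, non-convex coastlines, anisotropy, and real bathymetry or
temperature products. Passing tests therefore demonstrate correctness of
the machinery and recoverability under the model's own assumptions — not
robustness to the many ways real survey data violate them.

## Scaled experiment sizes

The stochastic test experiments are scaled to run on one CPU in minutes,
as the package's reference study conditions:

* Parameter recovery: 3 replicates of 10 years x 150 tows on 300 x 300 km
  with a single AR1 spatio-temporal field (SD 1.0, rho 0.7; truth mesh
  20 km, fitting mesh 25 km, 6 knots). Each hyperparameter and covariate
  optimum must fall in its 95% interval in a majority of replicates. Two
  design points matter. First, truth-mesh and fitting-mesh resolution are
  matched: unresolved fine-scale field variation otherwise leaks into the
  Gamma noise and biases `phi` downward. Second, the recovery data carry
  no separate time-constant spatial field: with ten years the
  decomposition into a persistent field plus an AR1 field is only weakly
  identified (on some realizations the spatial SD collapses to zero while
  rho inflates to absorb the persistence), so the joint configuration is
  exercised in the selection experiment rather than asserted for
  component-wise recovery.
* Selection consistency: 3 replicates of 10 years x 60 tows on
  180 x 180 km with a 45-km range — chosen so the domain holds roughly 16
  independent spatial patches, because the information separating AR1
  from random-walk dynamics scales with spatial replication times years —
  generated under the full AR1 structure (rho 0.8, spatio-temporal SD
  1.2); five candidate structures, 4-fold ELPD warm-started from each
  full-data fit. The generating structure must be best-or-within-2 AIC in
  a majority of replicates and its ELPD must beat the iid structure and
  every reduced structure. The random walk is deliberately exempt from
  the ELPD clause: it is the AR1's nearest neighbour, and at this scale
  their plug-in predictive densities tie within cross-validation noise
  (their AIC difference, which the first clause does assert, is the
  sharper discriminator).
* Index behaviour: 8 years x 100 tows with one year reduced to 2 tows so
  that a stratum goes unsampled; the model-based index must remain
  defined there while the design-based estimator collapses, agree with
  the design-based index (R^2 > 0.8) in well-covered years, and the
  index machinery must reproduce the known integrated biomass within 2%
  when fed the generating parameters.

## Known limitations

* Posterior draws and a few oracle checks densify matrices; the intended
  regime is meshes up to a few hundred vertices and a few dozen years,
  not the hundreds of thousands of grid cells a production assessment
  might use for estimation.
* Hyperparameter intervals are Wald intervals on transformed scales from
  a finite-difference Hessian of the profiled marginal; they can be poor
  when a variance component sits near zero (where the AR1 rho is also
  unidentified).
* The shape parameter `phi` is mildly underestimated whenever the fitting
  mesh is much coarser than the true field variation (see above).
* Cross-validated ELPD uses plug-in predictive densities, not an honest
  integration over latent uncertainty; differences between structures
  with similar fit are accordingly noisy.
* The catchability factor multiplies the index; whether such a conversion
  should divide an efficiency instead is a substantive question the
  package does not decide — the preset reproduces the printed operation.
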