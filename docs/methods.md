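# Methods

This note documents the models, priors, numerical choices and known
limitations of `threatspace`, in the order the pipeline runs.

## Threat scoring

A threat record is (species, second-order IUCN code, optional third-order
code, scope, severity, timing).  The scope x severity → expected %
population decline table ships as `src/threatspace/data/decline_table.yaml`.
Only three of its cells are fixed by the method description the package
implements (rapid declines over the whole range = 24%; no/negligible
declines over a majority or minority of the range = 0%); the remaining
defaults are constructed as round(scope-fraction midpoint × severity
decline-rate midpoint) with scope midpoints 0.95 / 0.70 / 0.25 and severity
rates 40 / 25 / 10 / 8 / ~1 / 0 (% per decade).  The three anchor cells and
monotonicity in scope are asserted every time the table loads; any cell can
be overridden by pointing `load_decline_table` at an edited copy.  Records
with an *Unknown* scope or severity are rejected at lookup: imputation is an
upstream concern and silently guessing a decline would corrupt the
covariates.

Within a species and second-order code, multiple records combine by maximum
(`combine="sum"` is available; it changes projections little because one
severe threat usually dominates).  Scenario transforms write a
`decline_override` on each affected record and never touch the stored
scope/severity, which makes every scenario idempotent and keeps the
baseline recoverable.  Because the table is monotone in scope, the induced
designs are ordered elementwise: complete ≤ partial ≤ minimal ≤ baseline.

Driver membership is configured per level-1 code (classes 1, 2, 3, 7 →
habitat loss and degradation; 5 → hunting and collection; 11 → climate
change and severe weather; 4, 6 → disturbance and accidental mortality;
8 → invasive species and disease; 9 → pollution; 10, 12 → other).  This is
the natural reading of the six driver names against the IUCN level-1
classification and is an assumption; edit `driver_map` in the YAML to
change it.  The *other* driver participates in all-driver scenarios but has
no driver-specific scenario.

## Ordinal probit mixed model

Latent liability per species: z = x'β + a + u_minlat + u_maxlat + u_lon + ε,
ε ~ N(0, 1) (the residual variance is not identified from ordinal data and
is fixed at 1).  Category boundaries are (-∞, 0, γ₂, γ₃, ∞) over
NT < VU < EN < CR: the lowest threshold is fixed at zero and the intercept
is free.

* **Sampler.**  Truncated-normal data augmentation for z (inverse-CDF
  sampling with tail clipping at 1e-15); conjugate Gaussian updates for β
  and all random effects; conjugate scaled inverse-chi-square updates for
  variances; cutpoints parameterized as log-spacings (δ_k = log(γ_{k+1} −
  γ_k)) and moved jointly by random-walk Metropolis against the ordinal
  likelihood with z integrated out, with a flat prior on the γ scale
  (log-Jacobian included).  The proposal step adapts toward 30% acceptance
  during burn-in only.
* **Phylogenetic term.**  a ~ N(0, s²C) with C the Brownian tree
  covariance.  C is eigendecomposed once; the conditional precision
  α² I + C⁻¹/s² is diagonal in that basis, so each update is O(n²).
* **Spatial terms.**  Continuous range covariates enter as i.i.d. random
  intercepts over binned-degree levels (`bin_width`, default 1°).  At
  desk-scale assemblages (hundreds of species) 1° bins are nearly
  singleton — a per-species overdispersion term the probit scale cannot
  separate from — so the synthetic-data generator defaults to 20° bins,
  which reproduces the per-bin occupancy a global assemblage has at 1°.
  Tests fit with the generator's bin width.
* **Priors.**  Fixed effects: zero-location Cauchy, scale 2.5 on
  standardized covariates (scale 10 for the intercept), implemented exactly
  as a normal/inverse-gamma scale mixture so all updates stay conjugate.
  Covariates are standardized internally and the scaler is stored; scenario
  designs are transformed with the fit-time scaler at prediction.  Random
  effect variances use parameter-expanded priors (effect = α·ũ with
  ũ ~ N(0, s̃²K), s̃² ~ inv-χ²(ν, V), α ~ N(α_μ, α_V)); hyperparameters are
  exposed verbatim in `OrdinalModelConfig`: phylogeny V=1, ν=1000, α ~
  N(1, 1) (the near-flat chi-square-like prior); spatial V=1, ν=1, α ~
  N(0, 625).
* **Chain arithmetic.**  Retained draws = (iterations − burn-in)/thinning,
  validated at construction; defaults give exactly 1,000.

**Identifiability.**  With a full-rank per-species phylogenetic effect the
latent scale sits on a ridge: inflating all of (β, γ, random effects)
together changes the likelihood only through the prior cost of the random
effects, and the posterior of the phylogenetic variance can drift well
above the generating value.  Scale-free quantities — category
probabilities, predictions, pMCMC signs — are unaffected, which is why
conditional prediction and scenario contrasts are stable.  Parameter
recovery is therefore assessed on the scale-normalized coefficients
β/√(1 + ΣV), the standard rescaling for latent-scale models; the
calibration tests document the residual slack this leaves (≥90% of active
coefficients within 3 posterior s.d., ≥80% interval coverage across
replicates sharing variance estimates).

**Derived quantities.**  cat[p, c, s] is computed per retained draw as
differences of Φ at the cutpoints minus the species' full linear predictor
(random effects included); rows are renormalized against floating-point
drift and sum to 1 within 1e-12.  Backward elimination refits after
removing the single worst covariate with pMCMC ≥ 0.1 (ties: the later
column), incrementing the seed per round, and logs the full trail.
Classification accuracy takes each species' modal argmax category across
draws, breaking all ties toward the higher-risk category.  Prediction under
a scenario design conditions on each species' posterior random effects:
those effects capture vulnerability not described by threats and must
persist when threats are abated.

## Projection

ex100 per category: CR 0.999, EN 0.667, VU 0.1, NT 0.01, LC 0.0001 (the LC
value equals a 1e-6 annual rate compounded over a century); a preset with
NT lowered to 0.0001 supports the sensitivity variant.  ex[p, s] is the
probability-weighted mixture over categories; iteration p uses posterior
draw p, so parameter uncertainty and Bernoulli stochasticity compound.
Scenarios draw from named, independently seeded streams derived from one
master seed; a common-random-numbers mode (shared uniform array) is the
recommended default when differencing scenarios (`avoidable_contribution`),
where it removes spurious between-stream noise and makes extinction sets
nested across nested scenarios.  Cohen's D uses the pooled standard error
by default (the iteration count is arbitrary, so s.e.-scaled effect sizes
are reported instead of P values); the conventional pooled-s.d. variant is
a flag.

## Morphospace

* **pPCA.**  Traits are log10-transformed and scaled to unit variance
  (strictly positive input required; zero-variance columns rejected).
  Pagel's λ is profiled by REML with a bounded scalar search on [0, 1]
  (tolerance 1e-6, non-convergence raised, never silently defaulted);
  the evolutionary covariance R = E'C(λ)⁻¹E/(n−1) with E centred at the
  GLS mean is eigendecomposed; scores are centred traits times
  eigenvectors.  Centring at the GLS (phylogenetic) mean follows the
  convention of the reference implementation this module is cross-checked
  against on a fixture (agreement to ~1e-3, limited by the optimizers'
  tolerance).  Eigenvector signs are fixed by making the
  largest-magnitude loading positive.  With λ = 0 on an ultrametric
  unit-depth tree the procedure reduces exactly to ordinary covariance
  PCA, which the tests use as an oracle.  Non-ultrametric trees are
  accepted (the covariance formula is general).
* **Bandwidth.**  One diagonal bandwidth vector for all species, computed
  from the species-score cloud by a two-stage direct plug-in selector
  (Gaussian kernel; normal-scale start for ψ₈, then ψ₆ and ψ₄ by pairwise
  kernel functionals, finally h = (R(K)/(ψ₄ n))^{1/5} per axis).  The
  pairwise stages are O(n²); clouds above 2,000 points are
  deterministically thinned for the pilot functionals.
* **Grids and TPDs.**  The grid spans the score cloud extended by 15% per
  side (so edge species' Gaussians stay on-grid), 50 divisions per axis by
  default.  A species' density is separable, evaluated at cell centers and
  multiplied by the cell volume; the smallest set of highest-density cells
  holding ≥ α of the mass (α = 0.95 by default — the reference
  implementation's convention, exposed everywhere) is kept and renormalized
  to 1.  Masses below 1e-300 are zeroed so float underflow cannot create
  spurious occupied cells.  Community densities are weighted sums; richness
  counts strictly positive cells times cell volume and is therefore
  invariant to positive weights and monotone under adding species.
* **FD loss and maps.**  Per-iteration loss uses a sparse cell x species
  incidence matrix (a cell survives if any occupant survives), processed in
  iteration chunks.  2-D density-loss maps are computed on a fresh
  100-bin-capable 2-axis grid rather than marginalized from 3-D; full
  density uses every species at the maximum survival count, and cells the
  full assemblage never occupies are masked as NaN.
* **Uniqueness.**  U_s = Σ_x w_s(x) · p_s(x)/P(x) over the species' support,
  with w_s its own normalized masses and P the unweighted community sum;
  1 for a species overlapping nothing, 1/n for n identical species.
  Species are trimmed before summation into the community (trimming after
  summation is a noted alternative that slightly reweights tails).
  Prioritization filters to VU/EN/CR and breaks score ties by species id.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
bird biogeography.  Trees are pure birth (Yule), binary, ultrametric, depth
normalized to 1.  Traits are matrix-normal Brownian with tunable λ
(default 0.8, a strong but imperfect signal typical of morphology) and a
0.6/0.4 compound-symmetry trait covariance at scale 0.1 on the log10 scale,
exponentiated before output.  Spatial covariates are uniform centroids with
exponential range extents — no spatial autocorrelation or realistic
coastlines.  About 21% of species are at risk (mirroring the Near
Threatened plus threatened share of the real assemblage), 0.4% are Data
Deficient.  At-risk species receive threat records with P(≥2 threats) =
0.94 and up to 6 codes; scope/severity/timing frequencies default to
uniform over the known levels because the real frequency distributions are
not reported — an explicitly arbitrary choice.  Every at-risk species is
guaranteed at least one record with positive expected decline.  Categories
come from the latent probit model on the standardized decline design with
3 active unit coefficients, cutpoints (0, 1.5, 3), phylogenetic variance
0.5 and per-term spatial variance 0.1 over 20° bins (see the
identifiability note above); all generating parameters are retained in
`truth` for recovery tests.

Passing tests on these worlds demonstrate that the algorithms are correct
under the assumed generative structure; they do not validate the ecological
assumptions themselves (threat-decline table values, driver membership,
spatial binning) against real data.

## Problem sizes

The test suite runs the sampler at n = 60–300 species with 1,000–20,000
iterations (20 replicates for the calibration suites) and
trait-density analyses on 60²–30³-cell grids; the examples use 200–250
species.  These sizes were chosen so the full chain of checks completes on
a single CPU in minutes while leaving the Monte Carlo error small relative
to every asserted tolerance; all of them scale up by configuration only.

## Known limitations

* The decline table's non-anchor cells and the driver map are constructed
  defaults, clearly marked as such, not transcriptions of a published
  supplement.
* Raw coefficient magnitudes from the ordinal model should be interpreted
  only jointly with the random-effect variances (see the identifiability
  note); compare scale-normalized values across fits.
* One shared bandwidth vector for all species; per-species bandwidths and
  functional evenness/divergence are out of scope.
* Scope/severity/timing imputation, taxonomy crosswalks and map rendering
  are out of scope; unknown levels must be resolved before scoring.
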