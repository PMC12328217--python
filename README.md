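# threatspace

Projected 100-year bird extinctions and functional-diversity loss under
threat-abatement scenarios.

`threatspace` is a reusable Python implementation of a comparative-methods
pipeline for conservation macroecology: from IUCN-style threat records
(scope x severity x timing per species) to a Bayesian ordinal model of Red
List category, stochastic 100-year extinction projections under
threat-reduction scenarios, and trait-probability-density measures of the
functional diversity those extinctions would erase.  It is written for
researchers who want to run, probe or extend this chain of methods without
assembling the original global datasets: a first-class synthetic-data module
generates phylogenies, traits, threats and Red List categories with known
truth, so every stage runs — and is validated — entirely offline.

## The pipeline

1. **Threat scoring** (`threats`).  Each threat record maps to an expected
   % population decline over 10 years / 3 generations via a scope x severity
   table (e.g. rapid declines across the whole range → 24%).  Within each
   second-order IUCN threat code the maximum decline is kept, giving
   pseudo-continuous covariates; codes affecting ≤10 species are grouped.
   Abatement scenarios transform records before scoring: *complete* zeroes
   every preventable decline (timing Ongoing / Future / Past-likely-to-return),
   *partial* downgrades Whole/Majority scopes to Minority, *minimal*
   downgrades Whole to Majority; scenarios can be restricted to drivers of
   extinction (habitat loss, hunting, climate change, ...).

2. **Extinction-risk model** (`risk`).  An ordinal probit mixed model of
   Red List category (NT < VU < EN < CR) with a latent liability

   z_s = x_s'β + a_s + u_s + ε_s,  ε_s ~ N(0, 1),

   where a ~ N(0, σ²_a C) is a phylogenetic effect (C the Brownian-motion
   tree covariance) and u collects i.i.d. random intercepts over
   binned-degree levels of minimum latitude, maximum latitude and centroid
   longitude.  Category c is observed when γ_{c-1} < z ≤ γ_c.  Sampling is
   Gibbs with truncated-normal data augmentation; cutpoints move by
   random-walk Metropolis on log-spacings; fixed effects carry zero-location
   Cauchy priors; random-effect variances carry parameter-expanded scaled
   inverse-chi-square priors.  Default chain: 103,000 iterations, burn-in
   3,000, thinning 100 → exactly 1,000 retained draws.  Covariates are
   removed by backward elimination on pMCMC (twice the smaller posterior
   tail beyond zero) at threshold 0.1.

3. **Projection** (`projection`).  Each draw p yields per-species category
   probabilities cat[p, c, s] (conditional on that species' own random
   effects, which persist under abatement); the 100-year extinction
   probability is the mixture

   ex[p, s] = Σ_c ex100_c · cat[p, c, s],

   with ex100 = 0.999 (CR), 0.667 (EN), 0.1 (VU), 0.01 (NT), 0.0001 (LC).
   Draw p then drives Bernoulli extinction outcomes for iteration p,
   compounding posterior uncertainty with demographic chance.  Species
   outside the model enter at probability 1 for their listed category
   (Data Deficient conservatively as Least Concern).

4. **Morphospace** (`ppca`, `morphospace`).  Eleven log10-scaled traits are
   ordinated by phylogenetic PCA (Pagel's λ fitted by REML, GLS centring);
   each species becomes a Gaussian trait-probability density on a
   50-division grid over the first three pPCs, bandwidth chosen by a
   plug-in selector, trimmed to its 95% highest-density cells.  Functional
   richness is the occupied volume of the summed community density;
   per-iteration FD loss removes the projected-extinct species.  Functional
   uniqueness — a species' density-weighted share of community density —
   ranks threatened species for targeted recovery, and density-loss maps
   show which morphologies the baseline scenario would thin out.

## A worked example

The scoring rule on the classic two-threat case (see
`examples/02_score_threats.py`):

```
  8.1.1: Majority (50-90%)  x slow significant declines  ->    7%
  8.1.2: Whole (>90%)       x rapid declines             ->   24%
combined (maximum rule) decline for 8.1: 24%

under each abatement scenario:
  baseline :   24%   (threats as listed)
  minimal  :   18%   (Whole scopes downgraded to Majority)
  partial  :    6%   (Whole/Majority scopes downgraded to Minority)
  complete :    0%   (preventable declines zeroed)
```

An end-to-end projection on a 250-species synthetic world
(`examples/05_project_extinctions.py`) prints, per scenario, the mean ±
s.d. number of extinctions across 1,000 paired iterations:

```
baseline :   10.4 +-  1.7 extinctions (4.2 +- 0.7% of assemblage)
complete :    5.5 +-  1.8 extinctions (2.2 +- 0.7% of assemblage)
partial  :    6.9 +-  1.9 extinctions (2.8 +- 0.8% of assemblage)
minimal  :    9.9 +-  1.8 extinctions (4.0 +- 0.7% of assemblage)
```

Complete abatement halves projected losses here; the residual extinctions
are carried by unpreventable past declines and by species-level
vulnerability captured in the random effects.  The remaining examples cover
world generation, pPCA, model fitting and the functional-diversity metrics;
each runs in seconds to about a minute.

## Layout

```
src/threatspace/   synthetic, threats, phylo, ppca, risk, projection,
                   morphospace; decline table config in data/
examples/          one narrative script per capability
docs/methods.md    model details, priors, numerical choices, limitations
```
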