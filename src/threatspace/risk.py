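"""Bayesian ordinal probit mixed model of Red List category on threat declines.

The extinction-risk model regresses the ordered Red List category (NT < VU <
EN < CR) of each at-risk species on its expected-decline covariates, with a
phylogenetic random effect (covariance proportional to the tree's
Brownian-motion matrix) and i.i.d. random intercepts over binned-degree
levels of three spatial covariates (minimum latitude, maximum latitude,
centroid longitude).  The link is probit with the residual variance fixed
at 1 — the ordinal-family convention, since the latent scale is not
identified from ordinal data.

Sampling is truncated-normal data augmentation (Albert & Chib): the latent
liability z_i is Gaussian around the linear predictor and constrained to the
cutpoint interval of the observed category.  Coefficients and random effects
then have conjugate Gaussian updates; variance components have conjugate
(scaled inverse-chi-square) updates, with the parameter-expansion working
scalar of each random term sampled as a Gaussian regression coefficient.
Cutpoints (lowest fixed at 0; the intercept is free) are sampled on
log-spacings by random-walk Metropolis against the marginal ordinal
likelihood, with an adaptive step during burn-in.

Priors follow weakly-informative conventions for ordinal regression:
zero-location Cauchy on fixed effects (implemented exactly as a
normal/inverse-gamma scale mixture), a high-degree-of-belief
parameter-expanded variance prior on the phylogenetic term and a
low-degree-of-belief parameter-expanded prior on the spatial terms; all
hyperparameters are exposed in :class:`OrdinalModelConfig`.

Each retained draw yields the per-species probability of membership in each
category, ``cat[p, c, s]``, as differences of the standard normal CDF at the
cutpoints minus the species' full linear predictor (random effects included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .phylo import PhyloCovariance

__all__ = [
    "OrdinalModelConfig",
    "PosteriorSamples",
    "fit_ordinal",
    "pmcmc",
    "backward_eliminate",
    "predict_scenario",
    "classification_accuracy",
    "MultiResponseConfig",
    "fit_multiresponse",
]

CATEGORIES = ("NT", "VU", "EN", "CR")

_EPS = 1e-300


@dataclass(frozen=True)
class VariancePrior:
    """Parameter-expanded scaled inverse-chi-square variance prior.

    The random term enters the predictor as ``alpha * u`` with
    ``u ~ N(0, s2 * K)``, ``s2 ~ inv-chi-square(nu, V)`` and the working
    scalar ``alpha ~ N(alpha_mu, alpha_V)``; the effective variance is
    ``alpha**2 * s2``.
    """

    V: float = 1.0
    nu: float = 1.0
    alpha_mu: float = 0.0
    alpha_V: float = 1.0


@dataclass(frozen=True)
class OrdinalModelConfig:
    n_iterations: int = 103_000
    burn_in: int = 3_000
    thinning: int = 100
    cauchy_scale: float = 2.5          # fixed-effect prior scale (standardized X)
    intercept_scale: float = 10.0
    phylo_prior: VariancePrior = field(
        default_factory=lambda: VariancePrior(V=1.0, nu=1000.0, alpha_mu=1.0,
                                              alpha_V=1.0)
    )
    spatial_prior: VariancePrior = field(
        default_factory=lambda: VariancePrior(V=1.0, nu=1.0, alpha_mu=0.0,
                                              alpha_V=625.0)
    )
    use_phylo: bool = True
    use_spatial: bool = True
    bin_width: float = 1.0             # degrees, for spatial grouping levels
    elimination_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self):
        kept = self.n_iterations - self.burn_in
        if kept <= 0 or kept % self.thinning != 0:
            raise ValueError(
                "(n_iterations - burn_in) must be a positive multiple of thinning"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorSamples:
    """Retained draws of the ordinal model and derived category probabilities.

    ``cat[p, c, s]`` is the probability that species ``s`` is in category
    ``c`` (NT, VU, EN, CR) at retained draw ``p``; rows sum to 1.
    """

    species: list[str]
    columns: list[str]
    beta: np.ndarray           # draws x (1 + p); intercept first
    cutpoints: np.ndarray      # draws x 3 (first is always 0)
    variances: pd.DataFrame    # draws x term (effective alpha^2 * s2)
    random_sum: np.ndarray     # draws x n species; total random effect
    cat: np.ndarray            # draws x 4 x n
    center: np.ndarray
    scale: np.ndarray
    config: OrdinalModelConfig

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


def _category_probs(eta: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """4 x n category probabilities for linear predictor eta."""
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    cdf = np.empty((5, eta.size))
    cdf[0] = 0.0
    cdf[4] = 1.0
    for k in (1, 2, 3):
        cdf[k] = ndtr(edges[k] - eta)
    return np.clip(np.diff(cdf, axis=0), 0.0, 1.0)


def _ordinal_loglik(eta, cuts, y_codes) -> float:
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    upper = ndtr(edges[y_codes + 1] - eta)
    lower = ndtr(edges[y_codes] - eta)
    return float(np.log(np.maximum(upper - lower, _EPS)).sum())


def _truncnorm(rng, mean, lower, upper):
    lo = ndtr(lower - mean)
    hi = ndtr(upper - mean)
    u = lo + (hi - lo) * rng.random(mean.size)
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return mean + ndtri(u)


class _PhyloTerm:
    """Parameter-expanded random effect with covariance s2 * C.

    Works in the eigenbasis of C (computed once): the conditional precision
    alpha^2 I + C^-1 / s2 is diagonal there, so each Gibbs update is O(n^2).
    """

    def __init__(self, C: np.ndarray, prior: VariancePrior):
        evals, evecs = np.linalg.eigh(C)
        self.evals = np.maximum(evals, 1e-10)
        self.Q = evecs
        self.prior = prior
        n = C.shape[0]
        self.u = np.zeros(n)
        self.alpha = prior.alpha_mu if prior.alpha_mu != 0 else 1.0
        self.s2 = prior.V

    @property
    def effect(self) -> np.ndarray:
        return self.alpha * self.u

    @property
    def variance(self) -> float:
        return self.alpha**2 * self.s2

    def update(self, rng, resid: np.ndarray) -> None:
        # u | rest
        prec = self.alpha**2 + 1.0 / (self.s2 * self.evals)
        proj = self.Q.T @ resid
        mean_q = self.alpha * proj / prec
        u_q = mean_q + rng.standard_normal(resid.size) / np.sqrt(prec)
        self.u = self.Q @ u_q
        # alpha | u  (scalar Gaussian regression)
        p = self.prior
        xx = self.u @ self.u
        prec_a = xx + 1.0 / p.alpha_V
        mean_a = (self.u @ resid + p.alpha_mu / p.alpha_V) / prec_a
        self.alpha = mean_a + rng.standard_normal() / np.sqrt(prec_a)
        # s2 | u  (scaled inverse-chi-square)
        quad = float(np.sum(u_q**2 / self.evals))
        shape = 0.5 * (p.nu + resid.size)
        rate = 0.5 * (p.nu * p.V + quad)
        self.s2 = rate / rng.gamma(shape)


class _GroupTerm:
    """Parameter-expanded i.i.d. random intercepts over grouping levels."""

    def __init__(self, idx: np.ndarray, n_levels: int, prior: VariancePrior):
        self.idx = idx
        self.m = n_levels
        self.counts = np.bincount(idx, minlength=n_levels).astype(float)
        self.prior = prior
        self.u = np.zeros(n_levels)
        self.alpha = prior.alpha_mu if prior.alpha_mu != 0 else 1.0
        self.s2 = prior.V

    @property
    def effect(self) -> np.ndarray:
        return self.alpha * self.u[self.idx]

    @property
    def variance(self) -> float:
        return self.alpha**2 * self.s2

    def update(self, rng, resid: np.ndarray) -> None:
        prec = self.alpha**2 * self.counts + 1.0 / self.s2
        sums = np.bincount(self.idx, weights=resid, minlength=self.m)
        mean = self.alpha * sums / prec
        self.u = mean + rng.standard_normal(self.m) / np.sqrt(prec)
        p = self.prior
        x = self.u[self.idx]
        prec_a = x @ x + 1.0 / p.alpha_V
        mean_a = (x @ resid + p.alpha_mu / p.alpha_V) / prec_a
        self.alpha = mean_a + rng.standard_normal() / np.sqrt(prec_a)
        shape = 0.5 * (p.nu + self.m)
        rate = 0.5 * (p.nu * p.V + float(self.u @ self.u))
        self.s2 = rate / rng.gamma(shape)


def _standardize(X: np.ndarray):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - center) / scale, center, scale


def fit_ordinal(
    design: pd.DataFrame,
    phylo_cov: PhyloCovariance | None,
    spatial: pd.DataFrame | None,
    categories: pd.Series,
    config: OrdinalModelConfig | None = None,
) -> PosteriorSamples:
    """Fit the extinction-risk model by Gibbs sampling.

    ``design`` rows, ``spatial`` rows and ``categories`` must share the same
    species index; ``phylo_cov`` is reordered to match.  Covariates are
    standardized internally (the Cauchy prior scale applies to standardized
    columns); the scaler is stored so that scenario designs are transformed
    identically at prediction time.
    """
    config = config or OrdinalModelConfig()
    species = list(design.index)
    y = categories.loc[species]
    unknown = set(y.unique()) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"categories outside modelled levels: {sorted(unknown)}")
    if y.nunique() < 2:
        raise ValueError("need at least 2 observed categories")
    y_codes = np.array([CATEGORIES.index(c) for c in y], dtype=int)
    n = len(species)

    Xz, center, scale = _standardize(design.to_numpy(dtype=float))
    W = np.column_stack([np.ones(n), Xz])
    p = W.shape[1]
    prior_scale = np.concatenate(
        [[config.intercept_scale], np.full(p - 1, config.cauchy_scale)]
    )

    terms: list = []
    if config.use_phylo:
        if phylo_cov is None:
            raise ValueError("use_phylo=True requires a phylogenetic covariance")
        C = phylo_cov.reordered(species).matrix
        ev = np.linalg.eigvalsh(C)
        if ev.min() < -1e-8 * max(ev.max(), 1.0):
            raise ValueError("phylogenetic covariance is not positive semi-definite")
        terms.append(("phylo", _PhyloTerm(C, config.phylo_prior)))
    if config.use_spatial:
        if spatial is None:
            raise ValueError("use_spatial=True requires spatial covariates")
        sp = spatial.loc[species]
        for col in ("min_lat", "max_lat", "centroid_lon"):
            bins = np.floor(sp[col].to_numpy(float) / config.bin_width).astype(int)
            levels, idx = np.unique(bins, return_inverse=True)
            terms.append((col, _GroupTerm(idx, len(levels), config.spatial_prior)))

    rng = np.random.default_rng(config.seed)
    beta = np.zeros(p)
    lam2 = np.ones(p)                     # Cauchy mixture local variances
    cuts = np.array([0.0, 1.0, 2.0])
    log_gaps = np.log(np.diff(np.concatenate([[0.0], cuts[1:]])))
    step = 0.1
    z = np.zeros(n)
    WtW = W.T @ W

    P = config.n_retained
    out_beta = np.empty((P, p))
    out_cuts = np.empty((P, 3))
    out_var = np.empty((P, len(terms)))
    out_rsum = np.empty((P, n))
    out_cat = np.empty((P, 4, n))
    kept = 0
    accepted = 0

    edges_lo = np.empty(n)
    edges_hi = np.empty(n)
    for it in range(config.n_iterations):
        rand_sum = np.zeros(n)
        for _, term in terms:
            rand_sum += term.effect
        eta = W @ beta + rand_sum

        # --- cutpoints: RW Metropolis on log-spacings, marginal likelihood
        prop = log_gaps + step * rng.standard_normal(2)
        cuts_prop = np.concatenate([[0.0], np.cumsum(np.exp(prop))])
        cur_ll = _ordinal_loglik(eta, cuts, y_codes) + log_gaps.sum()
        prop_ll = _ordinal_loglik(eta, cuts_prop, y_codes) + prop.sum()
        if np.log(rng.random()) < prop_ll - cur_ll:
            log_gaps = prop
            cuts = cuts_prop
            accepted += 1
        if it < config.burn_in and (it + 1) % 100 == 0:
            rate = accepted / 100
            step *= np.exp(0.5 * (rate - 0.3))
            accepted = 0

        # --- latent liabilities
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        edges_lo = edges[y_codes]
        edges_hi = edges[y_codes + 1]
        z = _truncnorm(rng, eta, edges_lo, edges_hi)

        # --- fixed effects (conjugate, Cauchy as scale mixture)
        resid_f = z - rand_sum
        A = WtW + np.diag(1.0 / (prior_scale**2 * lam2))
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, W.T @ resid_f)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        lam2 = 1.0 / rng.gamma(1.0, 1.0 / (0.5 + 0.5 * (beta / prior_scale) ** 2))

        # --- random terms, one at a time
        base = z - W @ beta
        effects = {name: term.effect for name, term in terms}
        for name, term in terms:
            resid = base - sum(e for k, e in effects.items() if k != name)
            term.update(rng, resid)
            effects[name] = term.effect

        # --- retain
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            rand_sum = np.zeros(n)
            for _, term in terms:
                rand_sum += term.effect
            eta = W @ beta + rand_sum
            out_beta[kept] = beta
            out_cuts[kept] = cuts
            out_var[kept] = [term.variance for _, term in terms]
            out_rsum[kept] = rand_sum
            out_cat[kept] = _category_probs(eta, cuts)
            kept += 1

    assert kept == P
    # guard against floating-point drift in the probability rows
    out_cat /= out_cat.sum(axis=1, keepdims=True)
    return PosteriorSamples(
        species=species,
        columns=list(design.columns),
        beta=out_beta,
        cutpoints=out_cuts,
        variances=pd.DataFrame(out_var, columns=[name for name, _ in terms]),
        random_sum=out_rsum,
        cat=out_cat,
        center=center,
        scale=scale,
        config=config,
    )


def pmcmc(draws: np.ndarray) -> float:
    """Twice the smaller posterior tail probability relative to zero."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    above = np.mean(draws > 0)
    below = np.mean(draws < 0)
    return float(2.0 * min(above, below))


def backward_eliminate(
    design: pd.DataFrame,
    phylo_cov: PhyloCovariance | None,
    spatial: pd.DataFrame | None,
    categories: pd.Series,
    config: OrdinalModelConfig | None = None,
    threshold: float | None = None,
):
    """Iteratively drop the least significant covariate and refit.

    At each round the column with the largest pMCMC at or above the
    threshold is removed (ties: the later column) and the model refit;
    the loop ends when every remaining covariate is significant or no
    columns remain.  Returns ``(samples, retained_columns, trail)`` where
    ``trail`` records each (dropped_column, pmcmc); ``samples`` is None if
    everything was eliminated.
    """
    config = config or OrdinalModelConfig()
    if threshold is None:
        threshold = config.elimination_threshold
    current = design.copy()
    trail: list[tuple[str, float]] = []
    round_seed = config.seed
    while True:
        if current.shape[1] == 0:
            return None, [], trail
        cfg = dc_replace(config, seed=round_seed)
        samples = fit_ordinal(current, phylo_cov, spatial, categories, cfg)
        ps = np.array([pmcmc(samples.beta[:, j + 1]) for j in range(current.shape[1])])
        worst = int(np.max(np.flatnonzero(ps == ps.max())))
        if ps[worst] < threshold:
            return samples, list(current.columns), trail
        trail.append((current.columns[worst], float(ps[worst])))
        current = current.drop(columns=[current.columns[worst]])
        round_seed += 1


def predict_scenario(
    samples: PosteriorSamples, scenario_design: pd.DataFrame
) -> np.ndarray:
    """Category probabilities under new covariates, conditioning on each
    species' own posterior random effects.

    The random effects capture vulnerability not described by threats, so
    they persist under abatement.  ``scenario_design`` must have exactly the
    fitted columns and species; it is transformed with the fit-time scaler.
    Returns ``cat[p, c, s]``.
    """
    if list(scenario_design.columns) != samples.columns:
        raise ValueError("scenario design columns do not match fitted design")
    if list(scenario_design.index) != samples.species:
        raise ValueError("scenario design species do not match fitted species")
    X = scenario_design.to_numpy(dtype=float)
    Xz = (X - samples.center) / samples.scale
    W = np.column_stack([np.ones(X.shape[0]), Xz])
    P = samples.n_draws
    out = np.empty_like(samples.cat)
    for pdx in range(P):
        eta = W @ samples.beta[pdx] + samples.random_sum[pdx]
        out[pdx] = _category_probs(eta, samples.cutpoints[pdx])
    out /= out.sum(axis=1, keepdims=True)
    return out


def classification_accuracy(
    cat: np.ndarray | PosteriorSamples, listed: pd.Series | np.ndarray
) -> float:
    """Fraction of species whose listed category matches the modal
    highest-probability category across draws.

    Ties — both within a draw (equal probabilities) and across draws (equal
    modal counts) — are broken toward the higher-risk category.
    """
    if isinstance(cat, PosteriorSamples):
        listed_arr = (
            listed.loc[cat.species].to_numpy()
            if isinstance(listed, pd.Series)
            else np.asarray(listed)
        )
        cat = cat.cat
    else:
        listed_arr = (
            listed.to_numpy() if isinstance(listed, pd.Series) else np.asarray(listed)
        )
    codes = np.array([CATEGORIES.index(c) for c in listed_arr], dtype=int)
    # reverse category axis so argmax prefers the higher-risk category on ties
    best = 3 - np.argmax(cat[:, ::-1, :], axis=1)          # draws x species
    n = cat.shape[2]
    modal = np.empty(n, dtype=int)
    for s in range(n):
        counts = np.bincount(best[:, s], minlength=4)
        modal[s] = 3 - np.argmax(counts[::-1])
    return float(np.mean(modal == codes))


# ---------------------------------------------------------------------------
# Gaussian multi-response model (morphospace bias in extinction avoidance)


@dataclass(frozen=True)
class MultiResponseConfig:
    """Chain and prior settings for the Gaussian multi-response model.

    Residual structure varies freely per response (diagonal across
    responses); the phylogenetic random-effect prior is diagonal with unit
    expected variance and degree of belief 2; fixed effects get an
    essentially flat zero-mean normal prior (variance 1e10).
    """

    n_iterations: int = 13_000
    burn_in: int = 3_000
    thinning: int = 10
    fixed_prior_var: float = 1e10
    re_prior: VariancePrior = field(
        default_factory=lambda: VariancePrior(V=1.0, nu=2.0, alpha_mu=0.0,
                                              alpha_V=1.0)
    )
    resid_nu: float = 0.002
    resid_V: float = 1.0
    seed: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


def fit_multiresponse(
    responses: pd.DataFrame,
    covariates: pd.DataFrame,
    phylo_cov: PhyloCovariance,
    config: MultiResponseConfig | None = None,
):
    """Gaussian multi-response mixed model: trait axes on avoidance counts.

    Each response column (a pPC score) is regressed on all covariate columns
    (per-driver counts of iterations in which extinction was avoided) with a
    phylogenetic random effect.  With diagonal residual and random-effect
    structures the responses factorize, so each is sampled by an independent
    conjugate Gibbs chain sharing the phylogenetic eigenbasis.

    Returns ``(slopes, summary)``: ``slopes[p, j, r]`` are posterior draws of
    covariate j's effect on response r, and ``summary`` is a tidy frame with
    posterior mean, 95% interval and pMCMC per (covariate, response).
    """
    config = config or MultiResponseConfig()
    if list(responses.index) != list(covariates.index):
        raise ValueError("responses and covariates must be species-aligned")
    species = list(responses.index)
    C = phylo_cov.reordered(species).matrix
    evals, Q = np.linalg.eigh(C)
    evals = np.maximum(evals, 1e-10)
    n = len(species)
    W = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    d = W.shape[1]
    Y = responses.to_numpy(dtype=float)
    R = Y.shape[1]
    P = config.n_retained

    slopes = np.empty((P, d - 1, R))
    WtW = W.T @ W
    for r in range(R):
        # one stream restarted per response: responses factorize, and
        # duplicated response columns then yield identical chains
        rng = np.random.default_rng(config.seed)
        y = Y[:, r]
        b = np.zeros(d)
        u = np.zeros(n)
        s2_u = 1.0
        s2_e = float(np.var(y)) or 1.0
        kept = 0
        pr = config.re_prior
        for it in range(config.n_iterations):
            # fixed effects
            A = WtW / s2_e + np.eye(d) / config.fixed_prior_var
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, W.T @ (y - u) / s2_e)
            b = mean + np.linalg.solve(L.T, rng.standard_normal(d))
            # phylogenetic effect in eigenbasis
            resid = y - W @ b
            prec = 1.0 / s2_e + 1.0 / (s2_u * evals)
            proj = Q.T @ resid / s2_e
            u_q = proj / prec + rng.standard_normal(n) / np.sqrt(prec)
            u = Q @ u_q
            # variance components
            quad = float(np.sum(u_q**2 / evals))
            s2_u = (0.5 * (pr.nu * pr.V + quad)) / rng.gamma(0.5 * (pr.nu + n))
            ee = float(np.sum((resid - u) ** 2))
            s2_e = (0.5 * (config.resid_nu * config.resid_V + ee)) / rng.gamma(
                0.5 * (config.resid_nu + n)
            )
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                slopes[kept, :, r] = b[1:]
                kept += 1

    rows = []
    for j, cov_name in enumerate(covariates.columns):
        for r, resp_name in enumerate(responses.columns):
            draws = slopes[:, j, r]
            rows.append(
                {
                    "covariate": cov_name,
                    "response": resp_name,
                    "mean": float(draws.mean()),
                    "lower95": float(np.quantile(draws, 0.025)),
                    "upper95": float(np.quantile(draws, 0.975)),
                    "pmcmc": pmcmc(draws),
                }
            )
    return slopes, pd.DataFrame(rows)
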