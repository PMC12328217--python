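"""100-year extinction projection under threat-abatement scenarios.

Each retained posterior draw p gives every species s a probability of
membership in each Red List category; mixing those with the per-category
100-year extinction probabilities gives

    ex[p, s] = sum_c ex100[c] * cat[p, c, s].

Draw p then supplies iteration p of a stochastic projection: each species is
independently assigned extinct with probability ex[p, s], so model
uncertainty and realized-extinction stochasticity are compounded.  Species
outside the risk model (Least Concern, or Data Deficient treated as Least
Concern) carry probability 1 at their listed category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EX100",
    "EX100_NT_LOW",
    "annual_to_horizon",
    "extinction_probability",
    "fixed_category_probs",
    "draw_extinctions",
    "ExtinctionDraws",
    "summarize",
    "avoidable_contribution",
    "cohens_d",
    "protect_species",
]

ALL_CATEGORIES = ("LC", "NT", "VU", "EN", "CR")

#: Probability of extinction within 100 years per Red List category.
EX100 = {"CR": 0.999, "EN": 0.667, "VU": 0.1, "NT": 0.01, "LC": 0.0001}

#: Sensitivity preset: Near Threatened assumed as safe as Least Concern.
EX100_NT_LOW = {**EX100, "NT": 0.0001}


def _check_ex100(ex100: dict) -> None:
    vals = [ex100[c] for c in ("CR", "EN", "VU", "NT", "LC")]
    if any(not 0 < v < 1 for v in vals):
        raise ValueError("ex100 probabilities must be in (0, 1)")
    if any(a < b for a, b in zip(vals, vals[1:])):
        raise ValueError("ex100 must not increase from CR down to LC")


def annual_to_horizon(annual_rate: float, years: int = 100) -> float:
    """Cumulative extinction probability from a constant annual rate."""
    return 1.0 - (1.0 - annual_rate) ** years


def extinction_probability(
    cat: np.ndarray,
    categories: list[str],
    ex100: dict | None = None,
) -> np.ndarray:
    """Mix category probabilities into 100-year extinction probabilities.

    ``cat`` has shape (draws, n_categories, n_species) with the category
    axis labelled by ``categories`` (any subset of LC..CR); every (draw,
    species) row must sum to 1 within 1e-9.  Returns ``ex[p, s]``.
    """
    ex100 = ex100 or EX100
    _check_ex100(ex100)
    cat = np.asarray(cat, dtype=float)
    sums = cat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("category probabilities must sum to 1 per (draw, species)")
    weights = np.array([ex100[c] for c in categories])
    return np.einsum("pcs,c->ps", cat, weights)


def fixed_category_probs(
    labels: pd.Series, n_draws: int, dd_as_lc: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Degenerate category probabilities for species outside the risk model.

    Each species gets probability 1 at its listed category in every draw;
    Data Deficient species are conservatively treated as Least Concern.
    """
    cats = list(ALL_CATEGORIES)
    probs = np.zeros((n_draws, len(cats), len(labels)))
    for s, lab in enumerate(labels):
        if lab == "DD":
            if not dd_as_lc:
                raise ValueError("Data Deficient species require dd_as_lc=True")
            lab = "LC"
        probs[:, cats.index(lab), s] = 1.0
    return probs, cats


@dataclass
class ExtinctionDraws:
    """Binary survival outcomes: species x iteration, one column per draw."""

    scenario: str
    species: list[str]
    survival: np.ndarray      # n_species x n_iterations, 1 = extant
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.survival.shape[1]

    @property
    def extinct_counts(self) -> np.ndarray:
        return (1 - self.survival).sum(axis=0)

    @property
    def survival_counts(self) -> np.ndarray:
        """Per species, the number of iterations in which it survived."""
        return self.survival.sum(axis=1)


def scenario_rng(master_seed: int, scenario: str) -> np.random.Generator:
    """A named, reproducible random stream per scenario."""
    digest = sum(ord(ch) * 31**i for i, ch in enumerate(scenario)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence((master_seed, digest)))


def draw_extinctions(
    ex: np.ndarray,
    species: list[str],
    seed: int,
    scenario: str = "baseline",
    paired_uniforms: np.ndarray | None = None,
) -> ExtinctionDraws:
    """Bernoulli extinction outcomes, iteration p driven by posterior draw p.

    ``ex`` has shape (draws, species).  With ``paired_uniforms`` (a shared
    uniform array of the same shape) scenarios use common random numbers, so
    that scenario contrasts are not inflated by independent noise.
    """
    ex = np.asarray(ex, dtype=float)
    if np.any((ex < 0) | (ex > 1)):
        raise ValueError("extinction probabilities must lie in [0, 1]")
    if paired_uniforms is None:
        u = scenario_rng(seed, scenario).random(ex.shape)
    else:
        if paired_uniforms.shape != ex.shape:
            raise ValueError("paired uniforms shape mismatch")
        u = paired_uniforms
    survival = (u >= ex).T.astype(np.int8)   # species x iterations
    return ExtinctionDraws(scenario=scenario, species=list(species),
                           survival=survival, seed=seed)


def summarize(draws: ExtinctionDraws, assemblage_size: int | None = None):
    """Mean and s.d. of extinctions across iterations, absolute and %.

    The percentage denominator is the full assemblage size (every species in
    the study), not just the modelled subset.
    """
    counts = draws.extinct_counts
    if counts.size == 0:
        raise ValueError("empty draws")
    denom = assemblage_size if assemblage_size is not None else len(draws.species)
    return {
        "scenario": draws.scenario,
        "mean_extinctions": float(counts.mean()),
        "sd_extinctions": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        "mean_percent": float(100.0 * counts.mean() / denom),
        "sd_percent": float(100.0 * counts.std(ddof=1) / denom)
        if counts.size > 1
        else 0.0,
    }


def avoidable_contribution(baseline: np.ndarray, scenario: np.ndarray) -> np.ndarray:
    """Per-iteration loss avoided: baseline loss minus scenario loss.

    Works on any per-iteration loss vectors (extinction counts or %
    functional-diversity loss).  Individual iterations may be negative.
    """
    baseline = np.asarray(baseline, dtype=float)
    scenario = np.asarray(scenario, dtype=float)
    if baseline.shape != scenario.shape:
        raise ValueError("mismatched iteration counts")
    return baseline - scenario


def cohens_d(a: np.ndarray, b: np.ndarray, denominator: str = "se") -> float:
    """Effect size of the difference in means of two loss distributions.

    ``denominator="se"`` divides by the pooled standard error (the
    convention used for scenario contrasts here, where the iteration count
    is arbitrary); ``"sd"`` gives the conventional pooled-s.d. variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sample")
    if denominator == "se":
        pooled = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    elif denominator == "sd":
        na, nb = a.size, b.size
        pooled = np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
    else:
        raise ValueError("denominator must be 'se' or 'sd'")
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled denominator")
    return float((a.mean() - b.mean()) / pooled)


def protect_species(
    ex: np.ndarray, species: list[str], protected: set[str] | list[str]
) -> np.ndarray:
    """Zero the extinction probability of protected species before drawing."""
    protected = set(protected)
    unknown = protected - set(species)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)[:5]}")
    out = np.array(ex, dtype=float, copy=True)
    idx = [i for i, s in enumerate(species) if s in protected]
    out[:, idx] = 0.0
    return out
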