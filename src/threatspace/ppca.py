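"""Phylogenetic principal component analysis (pPCA).

Ordinary PCA axes can be confounded by shared ancestry: related species
cluster in trait space for historical rather than functional reasons.  pPCA
removes phylogenetic covariance before extracting major axes.  Under a
multivariate Brownian model with Pagel's lambda, traits Y (n species x m
traits) have row covariance C(lambda) from the tree and an unknown trait
(column) covariance R.  The generalized-least-squares (phylogenetic) mean is

    a = (1' C^-1 1)^-1 1' C^-1 Y

and the evolutionary trait covariance

    R = (Y - 1a')' C^-1 (Y - 1a') / (n - 1).

lambda is profiled out by restricted maximum likelihood; R is then
eigendecomposed, and component scores are the centred traits projected on the
eigenvectors.  With a star phylogeny (or lambda = 0 on an ultrametric tree of
depth 1) this reduces exactly to ordinary covariance PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .phylo import PhyloCovariance, phylo_covariance

__all__ = ["Ordination", "preprocess_traits", "ppca", "select_components"]


def preprocess_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """log10-transform strictly positive traits, then scale to unit variance."""
    values = raw.to_numpy(dtype=float)
    if not np.all(values > 0):
        raise ValueError("traits must be strictly positive for log10 transform")
    logged = np.log10(values)
    sd = logged.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(raw.columns[sd == 0])
        raise ValueError(f"zero-variance trait column(s): {bad}")
    return pd.DataFrame(logged / sd, index=raw.index, columns=raw.columns)


@dataclass
class Ordination:
    """Result of a pPCA: loadings, scores, eigenvalues, and fitted lambda."""

    loadings: pd.DataFrame          # trait x component
    scores: pd.DataFrame            # species x component
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # percent, sums to 100
    lambda_hat: float
    phylo_mean: pd.Series           # GLS mean per trait

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_explained)


def _gls_mean_and_cov(Y: np.ndarray, C: np.ndarray):
    """GLS mean vector and evolutionary covariance for fixed C; also the
    REML profile log-likelihood terms that depend on C."""
    n, m = Y.shape
    cf = cho_factor(C, lower=True)
    Ci1 = cho_solve(cf, np.ones(n))
    denom = Ci1.sum()  # 1' C^-1 1
    a = Ci1 @ Y / denom
    E = Y - a
    CiE = cho_solve(cf, E)
    R = E.T @ CiE / (n - 1)
    logdet_C = 2.0 * np.log(np.diag(cf[0])).sum()
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        return a, R, -np.inf
    # REML profile log-likelihood up to an additive constant
    ll = -0.5 * (
        (n - 1) * logdet_R + m * logdet_C + m * np.log(denom) + (n - 1) * m
    )
    return a, R, ll


def ppca(
    traits: pd.DataFrame,
    tree,
    lam: float | None = None,
) -> Ordination:
    """Phylogenetic PCA of preprocessed traits on a tree.

    ``lam=None`` optimizes Pagel's lambda on [0, 1] by REML (bounded scalar
    search, tolerance 1e-6); a fixed value skips optimization (``lam=0`` is
    the ordinary-PCA oracle on ultrametric unit-depth trees).

    Raises ``RuntimeError`` if the optimizer fails to converge and
    ``ValueError`` if species are missing from the tree.
    """
    base = phylo_covariance(tree, 1.0)
    missing = set(traits.index) - set(base.species)
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)[:5]} ...")
    cov = base.reordered(list(traits.index))
    C1 = cov.matrix
    D = np.diag(np.diag(C1))
    Y = traits.to_numpy(dtype=float)

    def C_of(lam_):
        return lam_ * (C1 - D) + D

    if lam is None:
        res = minimize_scalar(
            lambda l: -_gls_mean_and_cov(Y, C_of(l))[2],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise RuntimeError(f"lambda REML optimization failed: {res.message}")
        lambda_hat = float(res.x)
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        lambda_hat = float(lam)

    a, R, ll = _gls_mean_and_cov(Y, C_of(lambda_hat))
    if not np.isfinite(ll):
        raise RuntimeError("singular evolutionary covariance")

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    scores = (Y - a) @ eigvec
    names = [f"pPC{j + 1}" for j in range(eigvec.shape[1])]
    ve = 100.0 * eigval / eigval.sum()
    return Ordination(
        loadings=pd.DataFrame(eigvec, index=traits.columns, columns=names),
        scores=pd.DataFrame(scores, index=traits.index, columns=names),
        eigenvalues=eigval,
        variance_explained=ve,
        lambda_hat=lambda_hat,
        phylo_mean=pd.Series(a, index=traits.columns),
    )


def select_components(ordination: Ordination, k: int = 3) -> pd.DataFrame:
    """First k component scores; cumulative variance kept in ``.attrs``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ordination.scores.shape[1]:
        raise ValueError("k exceeds number of components")
    reduced = ordination.scores.iloc[:, :k].copy()
    reduced.attrs["cumulative_variance"] = float(
        ordination.cumulative_variance[k - 1]
    )
    return reduced
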