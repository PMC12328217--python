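"""Trait-probability-density morphospace and functional-diversity metrics.

Each species occupies morphospace (the leading pPC axes) as a Gaussian
probability cloud: mean at its pPC scores, diagonal bandwidth shared by all
species and chosen by a plug-in selector from the species-score cloud.  The
cloud is discretized on a regular grid (50 divisions per axis by default),
trimmed to its highest-density cells holding a set fraction of mass (alpha,
default 0.95) and renormalized; the community density is the (weighted) sum
of species densities.  Functional richness is the volume of cells with
positive community mass.  Derived quantities:

* per-iteration functional-diversity loss when projected-extinct species are
  removed;
* 2-D density-loss maps of the morphologies most at risk;
* functional uniqueness — a species' density-weighted share of community
  density across its cells — and the top-k prioritization of unique
  threatened species for targeted recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "TraitGrid",
    "TPD",
    "build_grid",
    "bandwidth_select",
    "species_tpd",
    "community_tpd",
    "functional_richness",
    "fd_loss",
    "density_loss_map",
    "uniqueness",
    "prioritize_unique",
]


@dataclass(frozen=True, eq=False)
class TraitGrid:
    """Regular grid over k morphospace axes."""

    lower: np.ndarray       # per-axis lower bound
    upper: np.ndarray
    divisions: int

    def __eq__(self, other):
        return (
            isinstance(other, TraitGrid)
            and self.divisions == other.divisions
            and np.array_equal(self.lower, other.lower)
            and np.array_equal(self.upper, other.upper)
        )

    @property
    def k(self) -> int:
        return self.lower.size

    @property
    def steps(self) -> np.ndarray:
        return (self.upper - self.lower) / self.divisions

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.steps))

    @property
    def n_cells(self) -> int:
        return self.divisions**self.k

    def axis_centers(self, axis: int) -> np.ndarray:
        step = self.steps[axis]
        return self.lower[axis] + step * (np.arange(self.divisions) + 0.5)

    def contains(self, point: np.ndarray) -> bool:
        point = np.asarray(point, dtype=float)
        return bool(np.all(point >= self.lower) and np.all(point <= self.upper))


def build_grid(
    scores: pd.DataFrame | np.ndarray,
    divisions: int = 50,
    buffer_fraction: float = 0.15,
) -> TraitGrid:
    """Bounding grid of the score cloud, extended by a buffer each side.

    The buffer keeps the tails of edge species' Gaussians on the grid.
    """
    if divisions < 2:
        raise ValueError("divisions must be >= 2")
    X = np.asarray(scores, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    if np.any(span == 0):
        raise ValueError("constant axis: grid would be degenerate")
    return TraitGrid(
        lower=lo - buffer_fraction * span,
        upper=hi + buffer_fraction * span,
        divisions=divisions,
    )


# ---------------------------------------------------------------------------
# Plug-in bandwidth selection

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi_deriv_sum(x: np.ndarray, order: int) -> float:
    """Sum over pairwise scaled differences of the order-th Gaussian
    derivative (orders 4 and 6)."""
    x2 = x * x
    if order == 4:
        poly = x2 * x2 - 6.0 * x2 + 3.0
    elif order == 6:
        poly = x2 * x2 * x2 - 15.0 * x2 * x2 + 45.0 * x2 - 15.0
    else:  # pragma: no cover
        raise ValueError(order)
    return float(np.sum(poly * np.exp(-0.5 * x2) / _SQRT2PI))


def _plugin_1d(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth (Gaussian kernel), one axis."""
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    if sigma == 0:
        raise ValueError("degenerate axis: zero spread")
    # stage 0: normal-scale estimate of psi_8
    psi8 = 105.0 / (32.0 * np.sqrt(np.pi) * sigma**9)
    # stage 1: estimate psi_6 with pilot bandwidth g1
    k6_0 = -15.0 / _SQRT2PI
    g1 = (-2.0 * k6_0 / (psi8 * n)) ** (1.0 / 9.0)
    diffs = (x[:, None] - x[None, :]) / g1
    psi6 = _phi_deriv_sum(diffs, 6) / (n * n * g1**7)
    # stage 2: estimate psi_4 with pilot bandwidth g2
    k4_0 = 3.0 / _SQRT2PI
    g2 = (-2.0 * k4_0 / (psi6 * n)) ** (1.0 / 7.0)
    diffs = (x[:, None] - x[None, :]) / g2
    psi4 = _phi_deriv_sum(diffs, 4) / (n * n * g2**5)
    rk = 1.0 / (2.0 * np.sqrt(np.pi))
    return float((rk / (psi4 * n)) ** 0.2)


def bandwidth_select(scores: pd.DataFrame | np.ndarray, max_n: int = 2000) -> np.ndarray:
    """Diagonal plug-in bandwidth (one s.d. per axis) from the score cloud.

    The same bandwidth vector is applied to every species' Gaussian.  The
    pairwise stages are O(n^2); clouds larger than ``max_n`` points are
    deterministically subsampled for the pilot functionals.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 species for bandwidth selection")
    if X.shape[0] > max_n:
        idx = np.linspace(0, X.shape[0] - 1, max_n).astype(int)
        X = X[idx]
    return np.array([_plugin_1d(X[:, j]) for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# Trait probability densities


@dataclass
class TPD:
    """Probability mass on a grid, stored sparsely as (cell index, mass)."""

    owner: str
    grid: TraitGrid
    cells: np.ndarray        # flat cell indices, int64
    masses: np.ndarray       # same length; positive
    alpha: float
    mean: np.ndarray | None = None
    bandwidth: np.ndarray | None = None

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def dense(self) -> np.ndarray:
        out = np.zeros(self.grid.n_cells)
        np.add.at(out, self.cells, self.masses)
        return out


def species_tpd(
    mean: np.ndarray,
    bandwidth: np.ndarray,
    grid: TraitGrid,
    alpha: float = 0.95,
) -> TPD:
    """Gaussian occupancy of one species on the grid.

    The diagonal-covariance normal density is evaluated at cell centers and
    multiplied by the cell volume; the smallest set of highest-density cells
    holding at least ``alpha`` of the mass is kept and renormalized to 1.
    Underflow-level masses (< 1e-300) are zeroed to keep richness counts
    meaningful.
    """
    mean = np.asarray(mean, dtype=float)
    bandwidth = np.asarray(bandwidth, dtype=float)
    if np.any(bandwidth <= 0):
        raise ValueError("bandwidth must be positive on every axis")
    if not grid.contains(mean):
        raise ValueError("species mean lies outside the grid")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    # separable density: outer product of per-axis Gaussian pdfs
    dens = np.ones(1)
    for ax in range(grid.k):
        c = grid.axis_centers(ax)
        pdf = np.exp(-0.5 * ((c - mean[ax]) / bandwidth[ax]) ** 2) / (
            bandwidth[ax] * _SQRT2PI
        )
        dens = np.multiply.outer(dens, pdf)
    mass = (dens * grid.cell_volume).ravel()
    mass[mass < 1e-300] = 0.0
    total = mass.sum()
    if total <= 0:
        raise ValueError("species density underflows everywhere on the grid")
    mass /= total
    order = np.argsort(mass)[::-1]
    csum = np.cumsum(mass[order])
    n_keep = int(np.searchsorted(csum, alpha) + 1)
    keep = order[:n_keep]
    kept = mass[keep]
    kept /= kept.sum()
    by_cell = np.argsort(keep)
    return TPD(
        owner="species",
        grid=grid,
        cells=keep[by_cell].astype(np.int64),
        masses=kept[by_cell],
        alpha=alpha,
        mean=mean,
        bandwidth=bandwidth,
    )


def community_tpd(
    tpds: list[TPD], weights: np.ndarray | None = None
) -> TPD:
    """Weighted sum of species TPDs on a shared grid (weights default 1)."""
    if not tpds:
        raise ValueError("empty assemblage")
    grid = tpds[0].grid
    for t in tpds[1:]:
        if t.grid != grid:
            raise ValueError("all TPDs must share one grid")
    if weights is None:
        weights = np.ones(len(tpds))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    dense = np.zeros(grid.n_cells)
    for t, w in zip(tpds, weights):
        if w > 0:
            np.add.at(dense, t.cells, w * t.masses)
    cells = np.flatnonzero(dense)
    return TPD(
        owner="community",
        grid=grid,
        cells=cells.astype(np.int64),
        masses=dense[cells],
        alpha=tpds[0].alpha,
    )


def functional_richness(community: TPD) -> float:
    """Occupied-cell count times cell volume."""
    if community.cells.size == 0:
        raise ValueError("empty community TPD")
    return float(np.count_nonzero(community.masses > 0) * community.grid.cell_volume)


def _incidence(tpds: list[TPD]) -> sparse.csr_matrix:
    """Binary cells x species support matrix."""
    grid = tpds[0].grid
    rows = np.concatenate([t.cells for t in tpds])
    cols = np.concatenate(
        [np.full(t.cells.size, j, dtype=np.int64) for j, t in enumerate(tpds)]
    )
    data = np.ones(rows.size, dtype=np.int8)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(grid.n_cells, len(tpds))
    )


def fd_loss(
    tpds: list[TPD],
    survival: np.ndarray,
    chunk: int = 200,
) -> np.ndarray:
    """Percent functional-richness loss per iteration.

    ``survival`` is species x iterations with 1 = extant.  Loss is
    100 * (1 - richness(survivors) / richness(full assemblage)); an
    iteration losing every species scores 100.
    """
    survival = np.asarray(survival)
    if survival.shape[0] != len(tpds):
        raise ValueError("survival matrix not aligned with species TPDs")
    M = _incidence(tpds)
    full_cells = (M @ np.ones(len(tpds))) > 0
    full = int(full_cells.sum())
    n_iter = survival.shape[1]
    losses = np.empty(n_iter)
    for start in range(0, n_iter, chunk):
        S = survival[:, start : start + chunk].astype(np.float64)
        occupied = (M @ S) > 0
        losses[start : start + chunk] = 100.0 * (
            1.0 - occupied.sum(axis=0) / full
        )
    return losses


def density_loss_map(
    tpds: list[TPD],
    survival_counts: np.ndarray,
    max_count: int = 1000,
) -> np.ndarray:
    """Per-cell % loss in density of 2-D morphospace occupation.

    ``tpds`` must live on a 2-axis grid (by convention a fresh 100-bin grid
    over two pPCs).  ``survival_counts`` gives per species the number of
    iterations (0..max_count) in which it survived; the full assemblage has
    every species at ``max_count``.  Cells the full assemblage never
    occupies are NaN.
    """
    grid = tpds[0].grid
    if grid.k != 2:
        raise ValueError("density maps are computed on 2-axis grids")
    counts = np.asarray(survival_counts, dtype=float)
    if counts.size != len(tpds):
        raise ValueError("survival counts not aligned with species")
    if np.any((counts < 0) | (counts > max_count)):
        raise ValueError(f"survival counts must lie in [0, {max_count}]")
    full = community_tpd(tpds, np.full(len(tpds), float(max_count))).dense()
    kept = community_tpd(tpds, counts).dense() if counts.sum() > 0 else np.zeros_like(full)
    loss = np.full(grid.n_cells, np.nan)
    occ = full > 0
    loss[occ] = 100.0 * (1.0 - kept[occ] / full[occ])
    return loss.reshape(grid.divisions, grid.divisions)


def uniqueness(tpds: list[TPD], species: list[str]) -> pd.Series:
    """Functional uniqueness per species.

    For each cell where the species has positive density, take the species'
    share of the (unweighted) community density; average those shares with
    weights equal to the species' own cell masses.  A species overlapping
    nothing scores 1; n identical species score 1/n each.
    """
    if len(tpds) != len(species):
        raise ValueError("species labels not aligned with TPDs")
    P = community_tpd(tpds).dense()
    scores = np.empty(len(tpds))
    for j, t in enumerate(tpds):
        if t.total_mass <= 0:
            raise ValueError(f"species {species[j]!r} has zero total mass")
        w = t.masses / t.total_mass
        scores[j] = float(np.sum(w * t.masses / P[t.cells]))
    return pd.Series(scores, index=pd.Index(species, name="species"),
                     name="uniqueness")


def prioritize_unique(
    scores: pd.Series, categories: pd.Series, k: int
) -> list[str]:
    """Top-k most functionally unique threatened (VU/EN/CR) species.

    Ties are broken deterministically by species id.
    """
    threatened = [s for s in scores.index if categories.get(s) in ("VU", "EN", "CR")]
    if k > len(threatened):
        raise ValueError(f"k={k} exceeds threatened pool of {len(threatened)}")
    ranked = sorted(threatened, key=lambda s: (-scores[s], s))
    return ranked[:k]
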