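"""One-dimensional density estimation for two groups on a shared grid.

The shape component of the Impact effect size is the integrated absolute
difference between the probability density functions of the two groups
(a total-variation-style distance, bounded by 2).  For that integral to be
meaningful the two densities must be estimated on a *common* grid and with
the *same* amount of smoothing, which is what this module provides.

Two estimators are offered:

``pde``
    Pareto Density Estimation: at each grid point the density is
    proportional to the number of observations that fall within a fixed
    "Pareto radius" of the point.  The radius is a robust low quantile
    (default: 18th percentile) of the pairwise absolute-difference
    distribution of the pooled sample, so the smoothing adapts to the
    typical inter-point spacing rather than to the overall variance.  The
    estimator is deliberately under-smoothed compared to a rule-of-thumb
    kernel estimate, which makes it sensitive to fine shape features such
    as bimodality.

``kde``
    A standard Gaussian kernel density estimate with Silverman's
    bandwidth, fitted per group but evaluated on the shared grid.

Zero-variance groups (every observation identical) cannot support either
estimator; they are represented as a discrete unit point mass in the grid
cell that contains the value, so that degenerate inputs remain computable
instead of failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateDataError",
    "DensityPair",
    "pareto_radius",
    "shared_grid",
    "estimate_pdf_pair",
]

#: integral tolerance accepted for a normalized density
UNIT_MASS_TOL = 1e-6


class DegenerateDataError(ValueError):
    """Raised when a density request cannot be honoured (e.g. a Pareto
    radius from fewer than two distinct values)."""


@dataclass(frozen=True)
class DensityPair:
    """Two normalized densities evaluated on one shared grid.

    Attributes
    ----------
    grid :
        Strictly increasing evaluation points.
    pdf1, pdf2 :
        Non-negative density values (units 1/x) for group 1 and group 2;
        each integrates to 1 (trapezoidal rule) within ``UNIT_MASS_TOL``.
    method :
        ``"pde"`` or ``"kde"`` (degenerate point masses keep the label of
        the method that was requested).
    """

    grid: np.ndarray
    pdf1: np.ndarray
    pdf2: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.pdf1) == len(self.pdf2)):
            raise ValueError("grid and densities must have equal lengths")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        for name, pdf in (("pdf1", self.pdf1), ("pdf2", self.pdf2)):
            mass = float(np.trapezoid(pdf, self.grid))
            if abs(mass - 1.0) > UNIT_MASS_TOL:
                raise ValueError(f"{name} integrates to {mass!r}, not 1")


def pareto_radius(
    values,
    percentile: float = 18.0,
    cap: int = 5000,
    seed: int = 0,
) -> float:
    """Robust neighbourhood radius from the pairwise-distance distribution.

    Returns the ``percentile``-th percentile of ``|x_i - x_j|`` over all
    unordered pairs ``i < j``.  For samples larger than ``cap`` the
    quantile is computed on a seeded uniform subsample without
    replacement, keeping cost and memory bounded at ``cap**2 / 2`` terms.
    Heavily tied data can drive the quantile to zero; in that case a small
    fraction (5%) of the full data range is used instead, so the returned
    radius is always strictly positive.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < 2:
        raise DegenerateDataError("need at least 2 distinct values for a Pareto radius")
    full_range = float(x.max() - x.min())
    if x.size > cap:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=cap, replace=False)
    iu, ju = np.triu_indices(x.size, k=1)
    dists = np.abs(x[iu] - x[ju])
    radius = float(np.percentile(dists, percentile))
    if radius <= 0.0:
        radius = 0.05 * full_range
    return radius


def shared_grid(x1, x2, radius: float, n_points: int = 512) -> np.ndarray:
    """Equally spaced grid spanning the pooled data padded by one radius."""
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if radius <= 0:
        raise ValueError("radius must be positive")
    pooled = np.concatenate([np.asarray(x1, float).ravel(), np.asarray(x2, float).ravel()])
    return np.linspace(pooled.min() - radius, pooled.max() + radius, n_points)


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    dx = grid[1] - grid[0]
    w = np.full(grid.size, dx)
    w[0] = w[-1] = dx / 2.0
    return w


def _point_mass(grid: np.ndarray, value: float) -> np.ndarray:
    """Discrete unit mass in the grid cell containing ``value``."""
    w = _trapezoid_weights(grid)
    i = int(np.argmin(np.abs(grid - value)))
    pdf = np.zeros(grid.size)
    pdf[i] = 1.0 / w[i]
    return pdf


def _nearest_counts(grid: np.ndarray, x: np.ndarray) -> np.ndarray:
    # histogram-style fallback: each observation contributes to its
    # nearest grid point (used only if a smoothing pass yields zero mass)
    idx = np.clip(np.searchsorted(grid, x), 0, grid.size - 1)
    left = idx > 0
    idx[left] -= np.abs(grid[idx[left] - 1] - x[left]) < np.abs(grid[idx[left]] - x[left])
    dens = np.zeros(grid.size)
    np.add.at(dens, idx, 1.0)
    return dens


def _group_density(x: np.ndarray, grid: np.ndarray, radius: float, method: str) -> np.ndarray:
    if np.unique(x).size < 2:
        return _point_mass(grid, float(x[0]))
    if method == "pde":
        xs = np.sort(x)
        hi = np.searchsorted(xs, grid + radius, side="right")
        lo = np.searchsorted(xs, grid - radius, side="left")
        dens = (hi - lo).astype(float)
    elif method == "kde":
        dens = stats.gaussian_kde(x, bw_method="silverman")(grid)
    else:
        raise ValueError(f"unknown density method {method!r}")
    mass = float(np.trapezoid(dens, grid))
    if mass <= 0.0:  # radius smaller than grid spacing on very sparse data
        dens = _nearest_counts(grid, x)
        mass = float(np.trapezoid(dens, grid))
    return dens / mass


def estimate_pdf_pair(
    x1,
    x2,
    method: str = "pde",
    n_points: int = 512,
    percentile: float = 18.0,
    cap: int = 5000,
    seed: int = 0,
) -> DensityPair:
    """Estimate both group densities on a shared grid with shared smoothing.

    One Pareto radius is derived from the *pooled* sample so that the two
    groups are smoothed identically; the grid spans the pooled data padded
    by that radius.  Groups with zero variance become discrete unit point
    masses.  If the pooled sample itself is constant, both groups collapse
    onto the same point mass (their shape difference is then zero).
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x1, x2])
    if np.unique(pooled).size < 2:
        v = float(pooled[0])
        grid = np.linspace(v - 1.0, v + 1.0, n_points)
        spike = _point_mass(grid, v)
        return DensityPair(grid=grid, pdf1=spike, pdf2=spike.copy(), method=method)
    radius = pareto_radius(pooled, percentile=percentile, cap=cap, seed=seed)
    grid = shared_grid(x1, x2, radius, n_points)
    pdf1 = _group_density(x1, grid, radius, method)
    pdf2 = _group_density(x2, grid, radius, method)
    return DensityPair(grid=grid, pdf1=pdf1, pdf2=pdf2, method=method)
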