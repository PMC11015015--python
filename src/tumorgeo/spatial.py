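"""Local spatial statistics over the tumor slice.

Local Geary's C for sector i measures how genetically similar a sector is
to its spatial neighborhood:

    C_i = (2 n^2 / sum_{i != j} D_ij^2) * sum_{j != i} w_ij D_ij^2,

with spatial weight w_ij = 1 / (physical distance between i and j) and
D_ij the genetic distance.  Small C_i means strong local autocorrelation
(genetically similar neighbors).  Both sums run over ordered pairs.  Since
w has units 1/mm, C itself is unit-dependent; the permutation p-value —
shuffle the genetic identities over the fixed sector positions — is the
unit-free summary and the headline output.

Regional diversity theta_R maps heterogeneity across the slice: on a grid
(default 2 mm), theta_R at a point is the mean pairwise genetic distance
among sectors whose centers fall in a circular neighborhood whose default
diameter is the median inter-sector distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from skbio import DistanceMatrix

from .model import SectorMap

__all__ = [
    "GearyResult",
    "RegionalDiversityGrid",
    "local_gearys_c",
    "geary_permutation_test",
    "regional_diversity_grid",
    "classify_center_periphery",
]


def _aligned_squared(d: DistanceMatrix, sm: SectorMap):
    if set(d.ids) != set(sm.sectors):
        raise ValueError("distance matrix ids do not match the sector map")
    d = d.filter(list(sm.sectors))
    D2 = d.data**2
    phys = np.sqrt(((sm.coords[:, None, :] - sm.coords[None, :, :]) ** 2).sum(2))
    off = ~np.eye(len(sm), dtype=bool)
    if np.any(phys[off] == 0):
        raise ValueError("co-located sectors: inverse-distance weights undefined")
    with np.errstate(divide="ignore"):
        w = np.where(off, 1.0 / np.where(phys == 0, np.inf, phys), 0.0)
    return D2, w


def _geary_vector(D2: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, bool]:
    n = D2.shape[0]
    norm = D2.sum()  # ordered pairs; the diagonal is zero
    if norm == 0:
        return np.zeros(n), True
    return (2.0 * n * n / norm) * (w * D2).sum(axis=1), False


def local_gearys_c(d: DistanceMatrix, sm: SectorMap) -> np.ndarray:
    """Per-sector local Geary's C, ordered like ``sm.sectors``.

    When all genetic distances are zero the statistic is degenerate and
    every C_i is reported as 0.
    """
    D2, w = _aligned_squared(d, sm)
    c, _ = _geary_vector(D2, w)
    return c


@dataclass(frozen=True)
class GearyResult:
    """Local Geary's C values with spatial-permutation p-values.

    ``p[i]`` is the fraction of permutations (genetic identities shuffled
    over the fixed sector positions) in which the permuted C at position i
    is smaller than the observed one — small p marks neighborhoods whose
    genetic similarity would rarely arise by chance.  With the default
    add-one correction p = (1 + #{C_perm < C_obs}) / (B + 1) in (0, 1].
    """

    sectors: tuple[str, ...]
    c: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    n_permutations: int
    rng_seed: int
    degenerate: bool = False


def geary_permutation_test(
    d: DistanceMatrix,
    sm: SectorMap,
    B: int = 999,
    rng_seed: int = 0,
    add_one: bool = True,
) -> GearyResult:
    """Permutation test of local spatial autocorrelation.

    Sector positions stay fixed; the rows/columns of the genetic distance
    matrix are permuted B times, re-evaluating C at every position.
    ``add_one=False`` reports the plain proportion instead of the
    add-one-corrected p (which can then be exactly 0).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    D2, w = _aligned_squared(d, sm)
    c_obs, degenerate = _geary_vector(D2, w)
    n = len(sm)
    rng = np.random.default_rng(rng_seed)
    less = np.zeros(n)
    norm = D2.sum()
    scale = 0.0 if degenerate else 2.0 * n * n / norm
    for _ in range(B):
        perm = rng.permutation(n)
        D2p = D2[np.ix_(perm, perm)]
        c_perm = scale * (w * D2p).sum(axis=1)
        less += c_perm < c_obs
    if add_one:
        p = (1.0 + less) / (B + 1.0)
    else:
        p = less / B
    return GearyResult(
        sectors=sm.sectors, c=c_obs, p=p, n_permutations=B,
        rng_seed=rng_seed, degenerate=degenerate,
    )


@dataclass(frozen=True)
class RegionalDiversityGrid:
    """theta_R evaluated over a regular grid on the slice.

    ``theta`` has shape (n_y, n_x) with NaN where fewer than two sectors
    fall in the neighborhood; ``xs``/``ys`` are the grid coordinates in mm
    (row-major: ``theta[iy, ix]`` sits at ``(xs[ix], ys[iy])``).
    """

    xs: np.ndarray = field(repr=False)
    ys: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)
    radius: float
    grid_step: float

    def to_table(self):
        import pandas as pd

        rows = [
            (self.xs[ix], self.ys[iy], self.theta[iy, ix])
            for iy in range(len(self.ys))
            for ix in range(len(self.xs))
        ]
        return pd.DataFrame(rows, columns=["x", "y", "theta_R"])


def regional_diversity_grid(
    d: DistanceMatrix,
    sm: SectorMap,
    grid_step: float = 2.0,
    radius: float | None = None,
) -> RegionalDiversityGrid:
    """Map regional diversity theta_R across the slice.

    ``radius`` defaults to half the median pairwise sector distance (the
    neighborhood diameter equals the median distance).  The grid covers the
    sector bounding box padded by the radius and is anchored at
    (min_x - radius, min_y - radius).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if set(d.ids) != set(sm.sectors):
        raise ValueError("distance matrix ids do not match the sector map")
    d = d.filter(list(sm.sectors))
    if radius is None:
        radius = float(np.median(pdist(sm.coords))) / 2.0
    lo = sm.coords.min(axis=0) - radius
    hi = sm.coords.max(axis=0) + radius
    xs = lo[0] + grid_step * np.arange(int(np.floor((hi[0] - lo[0]) / grid_step)) + 1)
    ys = lo[1] + grid_step * np.arange(int(np.floor((hi[1] - lo[1]) / grid_step)) + 1)
    data = d.data
    iu = np.triu_indices(len(sm), k=1)
    theta = np.full((len(ys), len(xs)), np.nan)
    for iy, gy in enumerate(ys):
        for ix, gx in enumerate(xs):
            dist = np.hypot(sm.coords[:, 0] - gx, sm.coords[:, 1] - gy)
            inside = np.flatnonzero(dist <= radius)
            if len(inside) < 2:
                continue
            sub = data[np.ix_(inside, inside)]
            theta[iy, ix] = sub[np.triu_indices(len(inside), k=1)].mean()
    return RegionalDiversityGrid(
        xs=xs, ys=ys, theta=theta, radius=float(radius), grid_step=float(grid_step)
    )


def classify_center_periphery(sm: SectorMap) -> dict[str, str]:
    """Label sectors central or peripheral.

    The tumor center is the centroid of the sector coordinates and the
    tumor radius r the largest centroid-to-sector distance; sectors within
    r/2 of the center are ``central``, the rest ``peripheral``.
    """
    centroid = sm.coords.mean(axis=0)
    dist = np.hypot(*(sm.coords - centroid).T)
    r = dist.max()
    return {
        s: ("central" if di <= r / 2 else "peripheral")
        for s, di in zip(sm.sectors, dist)
    }
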