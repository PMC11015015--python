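"""Pairwise sector dissimilarities and the isolation-by-distance fit.

Four distance families are supported: physical (Euclidean, mm), genetic
(Hamming counts or the branch-mutation proportion, i.e. Jaccard distance,
between per-sector mutation sets), transcriptomic (1 - Spearman rho over
the most variable genes), and clonal (Euclidean distance between clone
proportion vectors).  Isolation by distance (IBD) is the positive
relationship between physical separation and dissimilarity; it is
quantified by ordinary least squares over all sector pairs, optionally
with a Mantel permutation p-value that respects the non-independence of
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel

from .model import CloneComposition, ExpressionMatrix, MutationMatrix, SectorMap

__all__ = [
    "IBDFit",
    "physical_distance",
    "genetic_distance",
    "transcriptomic_distance",
    "clonal_distance",
    "ibd_fit",
]


def physical_distance(sm: SectorMap) -> DistanceMatrix:
    """Euclidean distance between sector centers in the slice plane (mm)."""
    d = squareform(pdist(sm.coords, metric="euclidean"))
    return DistanceMatrix(d, ids=list(sm.sectors))


def genetic_distance(m: MutationMatrix, method: str = "hamming") -> DistanceMatrix:
    """Genetic distance between per-sector mutation sets.

    ``hamming``: the number of variants present in exactly one of the two
    sectors (the size of the symmetric difference of the mutation lists).
    ``branch_proportion``: that count divided by the number of variants in
    the union — the proportion of non-shared (branch) mutations among all
    mutations found in the two sectors, equal to the Jaccard distance; it
    is defined as 0 when both sectors carry no mutations.
    """
    x = m.presence.astype(np.float64)
    inter = x @ x.T
    totals = x.sum(axis=1)
    union = totals[:, None] + totals[None, :] - inter
    sym_diff = union - inter
    if method == "hamming":
        d = sym_diff
    elif method == "branch_proportion":
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, sym_diff / np.where(union > 0, union, 1), 0.0)
    else:
        raise ValueError(f"unknown genetic distance method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float round-off
    return DistanceMatrix(d, ids=list(m.sectors))


def transcriptomic_distance(
    e: ExpressionMatrix,
    n_top: int = 3000,
    gene_subset: list[str] | None = None,
) -> DistanceMatrix:
    """1 - Spearman correlation between sector expression profiles.

    Genes are ranked by their median absolute deviation (MAD) across
    sectors and the ``n_top`` most variable are retained (all genes if
    fewer are available); ties at the cutoff break by gene id so the
    selection is deterministic.  ``gene_subset`` bypasses the MAD ranking
    — this is how purity-correlated or copy-number-free gene lists are
    plugged in.  Values in [0, 2]; ranks use the average-tie convention.
    """
    if gene_subset is not None:
        index = {g: i for i, g in enumerate(e.genes)}
        missing = [g for g in gene_subset if g not in index]
        if missing:
            raise ValueError(f"genes not in the matrix: {missing[:5]}")
        rows = [index[g] for g in gene_subset]
        sub = e.values[rows, :]
    else:
        if n_top < 2:
            raise ValueError("n_top must be >= 2")
        med = np.median(e.values, axis=1, keepdims=True)
        mad = np.median(np.abs(e.values - med), axis=1)
        # sort by (-MAD, gene id): deterministic at tied MAD values
        order = sorted(range(len(e.genes)), key=lambda i: (-mad[i], e.genes[i]))
        sub = e.values[order[: min(n_top, len(e.genes))], :]
    sd = sub.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"sector {e.sectors[flat[0]]!r} has a zero-variance expression "
            "profile after gene selection; Spearman correlation is undefined"
        )
    rho = stats.spearmanr(sub, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sector case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    return DistanceMatrix(d, ids=list(e.sectors))


def clonal_distance(c: CloneComposition) -> DistanceMatrix:
    """Euclidean distance between clone-proportion vectors, sqrt(sum (p_i - q_i)^2)."""
    d = squareform(pdist(c.proportions, metric="euclidean"))
    return DistanceMatrix(d, ids=list(c.sectors))


@dataclass(frozen=True)
class IBDFit:
    """Least-squares fit of dissimilarity against physical distance.

    The regression treats each unordered sector pair as one point.  Pairs
    share sectors and are not independent, so ``p_value`` (from the OLS t
    statistic) is anti-conservative; ``mantel_p``, when computed, is the
    permutation p-value that accounts for the matrix structure.
    ``degenerate`` flags a constant response (slope and r reported as 0).
    """

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n_pairs: int
    mantel_p: float | None = None
    degenerate: bool = False


def ibd_fit(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    mantel_permutations: int = 0,
    rng_seed: int = 0,
) -> IBDFit:
    """Regress distances ``dy`` on distances ``dx`` over all sector pairs.

    Requires identical label sets; ``dy`` is reordered to ``dx``'s ids.
    ``mantel_permutations`` > 0 adds a one-sided (positive association)
    Mantel permutation test.
    """
    if set(dx.ids) != set(dy.ids):
        raise ValueError("distance matrices have different sector sets")
    dy = dy.filter(dx.ids)
    x = dx.condensed_form()
    y = dy.condensed_form()
    if x.size < 3:
        raise ValueError("IBD fit needs at least 3 sector pairs")
    n = len(dx.ids)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return IBDFit(0.0, float(np.mean(y)), 0.0, 0.0, 1.0,
                      n_pairs=x.size, degenerate=True)
    res = stats.linregress(x, y)
    mantel_p = None
    if mantel_permutations > 0:
        _, mantel_p, _ = mantel(
            dx, dy, method="pearson", permutations=mantel_permutations,
            alternative="greater", seed=rng_seed,
        )
        mantel_p = float(mantel_p)
    return IBDFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=int(x.size),
        mantel_p=mantel_p,
    )
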