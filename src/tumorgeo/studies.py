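"""Simulation studies validating the pipeline on synthetic tumors.

Each function runs a self-contained experiment — generate synthetic
patients with known ground truth, run the analysis, summarize how often
it recovers the truth.  They are used by the test suite and the
acceptance script, and are part of the public API so users can rerun the
calibration experiments with their own settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .distances import genetic_distance, ibd_fit, physical_distance
from .io import binarize_and_filter
from .model import MutationMatrix, SectorMap
from .selection import sackin_yule_test, yule_tree
from .simulate import GrowthConfig, simulate_patient, two_block_config
from .spatial import geary_permutation_test, regional_diversity_grid
from .trees import build_parsimony_tree, find_spatial_blocks

__all__ = [
    "CALLING_VAF_FLOOR",
    "BlockRecoveryOutcome",
    "analyze_two_block_patient",
    "ibd_direction_study",
    "block_recovery_study",
    "theta_ridge_study",
    "geary_null_pvalues",
    "sackin_type1_study",
]

# Per-sector presence calls require a clearly observed variant: at the
# default depth of ~100 reads a caller needs several supporting reads, so
# synthetic analyses call presence at VAF > 0.05 (cell fraction ~ 10%).
CALLING_VAF_FLOOR = 0.05


def _seed(base: int, i: int) -> int:
    return int((base + 7919 * i) % 2**31)


def ibd_direction_study(
    n_seeds: int = 100, base_seed: int = 0, mode: str = "boundary"
) -> np.ndarray:
    """Pearson r of genetic vs physical distance across simulated tumors.

    Boundary growth should give positive r essentially always; the
    well-mixed mode is the negative control with r centered on 0.
    """
    rs = np.empty(n_seeds)
    for i in range(n_seeds):
        cfg = GrowthConfig(rng_seed=_seed(base_seed, i), mode=mode)
        _, sm, _, vaf, _, _ = simulate_patient(cfg)
        m = binarize_and_filter(vaf, present_threshold=CALLING_VAF_FLOOR)
        fit = ibd_fit(physical_distance(sm), genetic_distance(m))
        rs[i] = fit.pearson_r
    return rs


@dataclass(frozen=True)
class BlockRecoveryOutcome:
    seed: int
    n_sectors: int
    chosen_k: int
    ari: float

    @property
    def success(self) -> bool:
        return self.chosen_k == 2 and self.ari >= 0.9


def analyze_two_block_patient(cfg: GrowthConfig):
    """Simulate one two-clone patient and run the block pipeline.

    Returns ``(sector_map, mutation_matrix, partition, true_labels,
    composition, population)`` where ``true_labels`` marks the sectors the
    driver clone has invaded (driver cell fraction > 0.1 — a sector
    containing a detectable derived subclone carries the derived
    genotype, so that is the recoverable ground truth).
    """
    pop, sm, _, vaf, comp, _ = simulate_patient(cfg)
    m = binarize_and_filter(vaf, present_threshold=CALLING_VAF_FLOOR)
    part = find_spatial_blocks(build_parsimony_tree(m).tree)
    true = (comp.proportions[:, 1] > 0.1).astype(int)
    return sm, m, part, true, comp, pop


def block_recovery_study(
    n_seeds: int = 20, base_seed: int = 0, driver_advantage: float = 2.0
) -> list[BlockRecoveryOutcome]:
    """Can tree cutting + CH recover the two spatially segregated clones?"""
    out = []
    for i in range(n_seeds):
        cfg = two_block_config(_seed(base_seed, i), driver_advantage=driver_advantage)
        sm, _, part, true, _, _ = analyze_two_block_patient(cfg)
        pred = np.array([part.labels[s] for s in sm.sectors])
        out.append(
            BlockRecoveryOutcome(
                seed=cfg.rng_seed,
                n_sectors=len(sm),
                chosen_k=part.chosen_k,
                ari=float(adjusted_rand_score(true, pred)),
            )
        )
    return out


def theta_ridge_study(
    n_seeds: int = 20, base_seed: int = 0, strip_width: float | None = None
) -> list[bool]:
    """Is regional diversity elevated on the interface between two blocks?

    For each simulated two-clone patient, grid points are split into an
    interface strip — defined points roughly equidistant (within
    ``strip_width``, default one grid step) from the nearest sectors of
    the two clones, both within the theta neighborhood — and the interior
    rest; the outcome is whether mean theta_R on the strip exceeds the
    interior mean.
    """
    results = []
    for i in range(n_seeds):
        cfg = two_block_config(_seed(base_seed, i))
        sm, m, _, _, comp, _ = analyze_two_block_patient(cfg)
        d = genetic_distance(m, "branch_proportion")
        grid = regional_diversity_grid(d, sm)
        width = grid.grid_step if strip_width is None else strip_width
        majority = comp.proportions[:, 1] > 0.5
        xy_a, xy_b = sm.coords[majority], sm.coords[~majority]
        iface, interior = [], []
        for iy, gy in enumerate(grid.ys):
            for ix, gx in enumerate(grid.xs):
                th = grid.theta[iy, ix]
                if np.isnan(th):
                    continue
                da = np.hypot(xy_a[:, 0] - gx, xy_a[:, 1] - gy).min()
                db = np.hypot(xy_b[:, 0] - gx, xy_b[:, 1] - gy).min()
                if max(da, db) <= grid.radius and abs(da - db) <= width:
                    iface.append(th)
                else:
                    interior.append(th)
        results.append(
            bool(iface) and bool(interior) and np.mean(iface) > np.mean(interior)
        )
    return results


def geary_null_pvalues(
    n_replicates: int = 200,
    B: int = 199,
    n_sectors: int = 10,
    n_variants: int = 40,
    base_seed: int = 0,
) -> np.ndarray:
    """Pooled permutation p-values under spatially unstructured nulls.

    Sector positions are uniform on a square and mutation profiles are
    i.i.d. coin flips, so no spatial autocorrelation exists and the
    per-sector p-values should be uniform on (0, 1].
    """
    pooled = []
    for i in range(n_replicates):
        rng = np.random.default_rng(_seed(base_seed, i))
        coords = rng.uniform(0, 20, size=(n_sectors, 2))
        sm = SectorMap("null", tuple(f"S{j}" for j in range(n_sectors)), coords)
        presence = rng.integers(0, 2, size=(n_sectors, n_variants))
        m = MutationMatrix(sm.sectors, tuple(f"m{j}" for j in range(n_variants)),
                           presence)
        res = geary_permutation_test(
            genetic_distance(m), sm, B=B, rng_seed=_seed(base_seed, i) + 1
        )
        pooled.extend(res.p)
    return np.asarray(pooled)


def sackin_type1_study(
    n_trials: int = 1000,
    n_leaves: int = 20,
    n_sim: int = 999,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> float:
    """Type-I error of the Sackin test on trees truly drawn from Yule."""
    rng = np.random.default_rng(base_seed)
    rejections = 0
    for i in range(n_trials):
        t = yule_tree(n_leaves, rng)
        res = sackin_yule_test(t, n_sim=n_sim, rng_seed=_seed(base_seed, i))
        rejections += res.p_value <= alpha
    return rejections / n_trials
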