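"""Synthetic spatially-expanding tumors with known ground truth.

The generator grows a 2-D cell population on a square lattice under an
Eden-style boundary-growth model: only cells with at least one empty
4-neighbor can divide, so lineages stay spatially coherent and the
population develops an isolation-by-distance pattern.  A ``mixed`` mode
(any cell may divide, the daughter lands at a random frontier site, and
cell positions are fully shuffled at the end) breaks every link between
lineage and location and serves as the spatially unstructured negative
control.

An optional driver subclone with division-probability advantage ``s`` can
arise once the population reaches a configurable size; under boundary
growth it expands into a contiguous wedge, giving tumors with two
spatially segregated clones — the ground truth for spatial-block recovery.

Sampling mimics multi-sector bulk sequencing of a central slice: circular
sectors on a honeycomb (hexagonal) grid, binomial read sampling of
variant allele frequencies at a configurable depth, exact per-sector clone
fractions, and clone-linked expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CloneComposition, ExpressionMatrix, SectorMap, VafMatrix

__all__ = [
    "GrowthConfig",
    "CellPopulation",
    "simulate_growth",
    "sample_honeycomb_sectors",
    "sectors_to_bulk",
    "simulate_expression",
    "simulate_patient",
    "two_block_config",
]

_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of the lattice growth model.

    Parameters
    ----------
    lattice_size : int
        Cells per lattice side (>= 16).
    target_cells : int or None
        Stop once this many cells exist; default fills a quarter of the
        lattice, leaving room so growth never hits the border.
    mutation_rate : float
        Mean number of new detectable somatic mutations per division
        (Poisson).  Kept well below 1: in sequenced tumors only a small
        minority of mutations arise during the imaged expansion at
        per-region detectable frequencies.
    founder_mutations : int
        Clonal (truncal) mutations carried by the founding cell, i.e. the
        load accumulated before the expansion that the slice captures.
        Real tumors are truncal-dominated: these variants are present in
        every cell and anchor the denominator of branch-proportion
        distances.
    driver_time : int or None
        Population size at which a driver subclone arises; None = neutral.
    driver_advantage : float
        Relative division weight s >= 1 of driver cells.
    driver_mutation_burst : float
        Mean number of extra mutations (Poisson) gained by the driver
        founder cell on top of the per-division rate.  Derived tumor
        clones typically differ from the ancestral lineage by a punctuated
        load of alterations (elevated genome instability), which is what
        makes the clone boundary the dominant genetic divergence in the
        tumor; 0 models a driver differing only by its regular divisional
        mutations.
    min_driver_fraction, max_driver_fraction : float
        When a driver is requested, the run conditions on clone
        coexistence: growth is resampled (deterministically, from the same
        seed stream) until the driver's final cell fraction lies in
        [min, max].  A lineage born at the rim of a growing blob is often
        engulfed and frozen at negligible size, or sweeps to fixation;
        conditioning reproduces tumors in which both lineages occupy
        macroscopic regions, as observed multi-clone tumors do.  Set
        (0, 1) to disable.
    mode : str
        ``boundary`` (Eden growth) or ``mixed`` (spatially randomized).
    cell_mm : float
        Physical edge length of one lattice cell in millimetres.  One
        lattice cell stands for a coherent patch of ~1e5 real cells; the
        default makes a full-grown tumor a few centimetres across.
    rng_seed : int
        Seed for all randomness in the growth run.
    """

    lattice_size: int = 128
    target_cells: int | None = None
    mutation_rate: float = 0.2
    founder_mutations: int = 200
    driver_time: int | None = None
    driver_advantage: float = 1.0
    driver_mutation_burst: float = 0.0
    min_driver_fraction: float = 0.15
    max_driver_fraction: float = 1.0
    mode: str = "boundary"
    cell_mm: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if self.lattice_size < 16:
            raise ValueError("lattice_size must be >= 16")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.founder_mutations < 0:
            raise ValueError("founder_mutations must be >= 0")
        if self.driver_advantage < 1:
            raise ValueError("driver_advantage must be >= 1")
        if not (0 <= self.min_driver_fraction < 1):
            raise ValueError("min_driver_fraction must lie in [0, 1)")
        if not (self.min_driver_fraction < self.max_driver_fraction <= 1):
            raise ValueError("need min_driver_fraction < max_driver_fraction <= 1")
        if self.driver_mutation_burst < 0:
            raise ValueError("driver_mutation_burst must be >= 0")
        if self.mode not in ("boundary", "mixed"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.cell_mm <= 0:
            raise ValueError("cell_mm must be positive")

    @property
    def n_cells(self) -> int:
        if self.target_cells is not None:
            return self.target_cells
        return self.lattice_size * self.lattice_size // 4


@dataclass
class CellPopulation:
    """Result of a growth run.

    ``positions`` are integer lattice coordinates, one row per cell;
    ``genotypes[i]`` indexes the genotype table; ``clones[i]`` is 0 for the
    ancestral lineage and 1 for the driver lineage.  Genotypes form a tree:
    ``genotype_parent[g]`` is the parent genotype (-1 for the founder) and
    ``genotype_muts[g]`` the mutations gained at the founding division, so a
    cell's full mutation set is the union along its ancestry (ancestry
    closure: every child's set contains its parent's).
    """

    config: GrowthConfig
    positions: np.ndarray
    genotypes: np.ndarray
    clones: np.ndarray
    genotype_parent: list[int]
    genotype_muts: list[tuple[int, ...]]
    n_mutations: int
    _closures: dict[int, frozenset[int]] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.positions)

    def mutation_closure(self, genotype: int) -> frozenset[int]:
        """Full mutation set of a genotype (its own plus all ancestors')."""
        cached = self._closures.get(genotype)
        if cached is not None:
            return cached
        chain, g = [], genotype
        while g >= 0 and g not in self._closures:
            chain.append(g)
            g = self.genotype_parent[g]
        acc = set(self._closures[g]) if g >= 0 else set()
        for g in reversed(chain):
            acc.update(self.genotype_muts[g])
            self._closures[g] = frozenset(acc)
        return self._closures[genotype]

    @property
    def coords_mm(self) -> np.ndarray:
        """Cell centers in millimetres, origin at the lattice seed."""
        center = self.config.lattice_size // 2
        return (self.positions - center) * self.config.cell_mm


def simulate_growth(cfg: GrowthConfig, max_attempts: int = 1000) -> CellPopulation:
    """Grow one tumor according to ``cfg``; reproducible given the seed.

    When a driver is requested the run is conditioned on the driver
    lineage establishing (see :class:`GrowthConfig`): up to
    ``max_attempts`` growth runs are drawn from the seeded stream until
    the final driver fraction reaches ``cfg.min_driver_fraction``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    for _ in range(max_attempts):
        pop = _grow_once(cfg, rng)
        if cfg.driver_time is None or (
            cfg.min_driver_fraction == 0 and cfg.max_driver_fraction == 1
        ):
            return pop
        if cfg.min_driver_fraction <= pop.clones.mean() <= cfg.max_driver_fraction:
            return pop
    raise RuntimeError(
        f"driver fraction never landed in [{cfg.min_driver_fraction}, "
        f"{cfg.max_driver_fraction}] within {max_attempts} attempts; "
        "widen the band or adjust driver_advantage"
    )


def _grow_once(cfg: GrowthConfig, rng: np.random.Generator) -> CellPopulation:
    L = cfg.lattice_size
    target = min(cfg.n_cells, L * L)
    occupied = np.zeros((L, L), dtype=bool)
    center = L // 2
    positions = [(center, center)]
    genotypes = [0]
    clones = [0]
    occupied[center, center] = True
    genotype_parent = [-1]
    genotype_muts: list[tuple[int, ...]] = [tuple(range(cfg.founder_mutations))]
    n_mut = cfg.founder_mutations
    driver_placed = cfg.driver_time is None
    s = cfg.driver_advantage

    def empty_neighbors(pos):
        x, y = pos
        out = []
        for dx, dy in _NEIGHBORS:
            nx, ny = x + dx, y + dy
            if 0 <= nx < L and 0 <= ny < L and not occupied[nx, ny]:
                out.append((nx, ny))
        return out

    # boundary mode: occupied cells that may still have an empty neighbor
    # (stale entries pruned lazily on draw)
    frontier = [0]
    # mixed mode: empty sites adjacent to the blob, kept incrementally
    empty_frontier = empty_neighbors((center, center))
    empty_pos = {site: k for k, site in enumerate(empty_frontier)}

    def claim_site(site):
        occupied[site] = True
        if cfg.mode == "mixed":
            k = empty_pos.pop(site)
            last = empty_frontier.pop()
            if last != site:
                empty_frontier[k] = last
                empty_pos[last] = k
            for nb in empty_neighbors(site):
                if nb not in empty_pos:
                    empty_pos[nb] = len(empty_frontier)
                    empty_frontier.append(nb)

    while len(positions) < target:
        if cfg.mode == "boundary":
            # weighted pick among frontier cells, rejection on staleness
            parent = -1
            while frontier:
                k = rng.integers(len(frontier))
                idx = frontier[k]
                empties = empty_neighbors(positions[idx])
                if not empties:
                    frontier[k] = frontier[-1]
                    frontier.pop()
                    continue
                if s > 1 and clones[idx] == 0 and rng.random() >= 1.0 / s:
                    continue  # driver cells divide s-fold faster
                parent = idx
                break
            if parent < 0:
                break  # lattice locally full
            site = empties[rng.integers(len(empties))]
        else:
            # mixed: any cell divides; daughter takes a random frontier site
            while True:
                idx = rng.integers(len(positions))
                if s <= 1 or clones[idx] == 1 or rng.random() < 1.0 / s:
                    parent = idx
                    break
            if not empty_frontier:
                break
            site = empty_frontier[rng.integers(len(empty_frontier))]

        n_new = rng.poisson(cfg.mutation_rate)
        child_clone = clones[parent]
        if not driver_placed and len(positions) >= cfg.driver_time:
            driver_placed = True
            child_clone = 1
            # punctuated divergence of the derived clone, >= 1 marker mutation
            n_new = max(n_new + rng.poisson(cfg.driver_mutation_burst), 1)
        if n_new > 0 or child_clone != clones[parent]:
            gid = len(genotype_parent)
            genotype_parent.append(genotypes[parent])
            genotype_muts.append(tuple(range(n_mut, n_mut + n_new)))
            n_mut += n_new
        else:
            gid = genotypes[parent]
        positions.append(site)
        genotypes.append(gid)
        clones.append(child_clone)
        claim_site(site)
        if cfg.mode == "boundary":
            frontier.append(len(positions) - 1)

    positions = np.asarray(positions, dtype=np.int64)
    if cfg.mode == "mixed":
        # complete spatial mixing: cells keep their genotypes but occupy
        # random sites of the blob, severing every link between lineage
        # and location (including the radial age gradient of growth)
        positions = positions[rng.permutation(len(positions))]
    return CellPopulation(
        config=cfg,
        positions=positions,
        genotypes=np.asarray(genotypes, dtype=np.int64),
        clones=np.asarray(clones, dtype=np.int64),
        genotype_parent=genotype_parent,
        genotype_muts=genotype_muts,
        n_mutations=n_mut,
    )


def sample_honeycomb_sectors(
    pop: CellPopulation,
    sector_radius: float = 1.5,
    pitch: float = 4.0,
    min_cells: int = 10,
    min_fill: float = 0.85,
    patient_id: str = "synthetic",
) -> tuple[SectorMap, list[np.ndarray]]:
    """Place circular sectors on a hexagonal grid over the tumor slice.

    ``sector_radius`` and ``pitch`` (center-to-center spacing) are in mm.
    A sector is retained only if it captures at least ``min_cells`` cells
    AND the cells fill at least ``min_fill`` of its area — tissue punches
    are taken from inside the tumor, so sectors straddling the rim (which
    would contain mostly non-tumor material and yield artificially noisy
    profiles) are not sampled.  Returns the sector map plus, per sector,
    the indices of cells inside it.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if sector_radius > pitch / 2:
        raise ValueError("sector_radius must be <= pitch/2 (non-overlapping sectors)")
    if not (0 <= min_fill <= 1):
        raise ValueError("min_fill must lie in [0, 1]")
    xy = pop.coords_mm
    centroid = xy.mean(axis=0)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    row_step = pitch * np.sqrt(3) / 2
    # cells a full sector is expected to hold (one cell per cell_mm^2 patch)
    full_count = np.pi * sector_radius**2 / pop.config.cell_mm**2
    centers, members = [], []
    n_rows = int(np.ceil((hi[1] - lo[1]) / row_step)) + 1
    n_cols = int(np.ceil((hi[0] - lo[0]) / pitch)) + 1
    for r in range(-n_rows, n_rows + 1):
        cy = centroid[1] + r * row_step
        x_off = (r % 2) * pitch / 2
        for c in range(-n_cols, n_cols + 1):
            cx = centroid[0] + x_off + c * pitch
            d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
            inside = np.flatnonzero(d2 <= sector_radius**2)
            if len(inside) >= max(min_cells, min_fill * full_count):
                centers.append((cx, cy))
                members.append(inside)
    if len(centers) < 2:
        raise ValueError(
            f"honeycomb sampling retained {len(centers)} sector(s); "
            "need >= 2 (reduce pitch or min_cells)"
        )
    order = np.lexsort(([c[0] for c in centers], [c[1] for c in centers]))
    centers = [centers[i] for i in order]
    members = [members[i] for i in order]
    names = tuple(f"S{i + 1:02d}" for i in range(len(centers)))
    sm = SectorMap(patient_id, names, np.asarray(centers, dtype=float))
    return sm, members


def sectors_to_bulk(
    pop: CellPopulation,
    sectors: SectorMap,
    members: list[np.ndarray],
    depth: float = 100.0,
    purity: float = 1.0,
    rng_seed: int = 0,
) -> tuple[VafMatrix, CloneComposition]:
    """Emulate bulk sequencing of each sector.

    Variants are modeled as diploid heterozygous, so a variant carried by a
    cell fraction f has expected VAF 0.5*f*purity.  Observed VAFs are
    binomial draws at a Poisson(``depth``) read depth per site; zero-depth
    cells are missing.  Clone proportions are exact cell-count fractions
    (purity-independent: they describe the tumor-cell compartment).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_sec = len(sectors)

    counts: dict[int, np.ndarray] = {}
    sizes = np.array([len(m) for m in members], dtype=float)
    for si, cell_idx in enumerate(members):
        gids, gcounts = np.unique(pop.genotypes[cell_idx], return_counts=True)
        for g, c in zip(gids, gcounts):
            for mut in pop.mutation_closure(int(g)):
                arr = counts.get(mut)
                if arr is None:
                    arr = counts[mut] = np.zeros(n_sec)
                arr[si] += c

    muts = sorted(counts)
    width = max(6, len(str(pop.n_mutations)))
    variant_ids = tuple(f"m{m:0{width}d}" for m in muts)
    if muts:
        frac = np.stack([counts[m] / sizes for m in muts], axis=1)  # sectors x variants
        p = 0.5 * frac * purity
        reads = rng.poisson(depth, size=p.shape)
        alt = rng.binomial(reads, p)
        with np.errstate(invalid="ignore"):
            vaf = np.where(reads > 0, alt / np.maximum(reads, 1), np.nan)
    else:
        # degenerate zero-mutation-rate run: emit a single all-absent variant
        variant_ids = ("m000000",)
        vaf = np.zeros((n_sec, 1))
    vafm = VafMatrix(sectors.sectors, variant_ids, vaf)

    clone_names = ("ancestral", "driver")
    props = np.zeros((n_sec, 2))
    for si, cell_idx in enumerate(members):
        props[si, 1] = pop.clones[cell_idx].mean()
        props[si, 0] = 1.0 - props[si, 1]
    comp = CloneComposition(sectors.sectors, clone_names, props)
    return vafm, comp


def simulate_expression(
    composition: CloneComposition,
    n_genes: int = 200,
    de_fraction: float = 0.2,
    effect_size: float = 1.0,
    noise_sd: float = 0.1,
    rng_seed: int = 0,
) -> ExpressionMatrix:
    """Clone-linked expression profiles for each sector.

    Each clone gets a centroid profile; clones beyond the first differ from
    it at a ``de_fraction`` of genes by +/- ``effect_size`` (log-normal
    baseline, additive shift).  A sector's profile is the clone-proportion
    weighted mix of centroids plus Gaussian noise, clipped at zero — the
    phenotype mirrors the genotype exactly up to noise.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(rng_seed)
    n_clones = len(composition.clones)
    base = rng.lognormal(mean=1.0, sigma=0.8, size=n_genes)
    centroids = np.tile(base, (n_clones, 1))
    for c in range(1, n_clones):
        n_de = int(round(de_fraction * n_genes))
        de_genes = rng.choice(n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        centroids[c, de_genes] += signs * effect_size
    profiles = composition.proportions @ centroids  # sectors x genes
    profiles = profiles + rng.normal(0.0, noise_sd, size=profiles.shape)
    values = np.clip(profiles.T, 0.0, None)  # genes x sectors
    genes = tuple(f"g{i + 1:04d}" for i in range(n_genes))
    return ExpressionMatrix(genes, composition.sectors, values)


def two_block_config(rng_seed: int = 0, driver_advantage: float = 2.0) -> GrowthConfig:
    """The canonical two-block (spatially competing) scenario.

    A driver subclone arises once the tumor has ~150 cells, carries a
    punctuated burst of ~100 extra clonal mutations (derived clones show
    markedly elevated genomic instability), divides twice as fast, and the
    run conditions on coexistence — a final driver fraction in
    [0.2, 0.8] — so both lineages occupy macroscopic, spatially
    contiguous regions of the slice.
    """
    return GrowthConfig(
        rng_seed=rng_seed,
        driver_time=150,
        driver_advantage=driver_advantage,
        driver_mutation_burst=100.0,
        min_driver_fraction=0.2,
        max_driver_fraction=0.8,
    )


def simulate_patient(
    cfg: GrowthConfig,
    sector_radius: float = 1.5,
    pitch: float = 4.0,
    min_cells: int = 10,
    depth: float = 100.0,
    purity: float = 1.0,
    n_genes: int = 200,
    effect_size: float = 1.0,
    noise_sd: float = 0.1,
    patient_id: str = "synthetic",
):
    """Grow, sample and sequence one synthetic patient.

    Returns ``(pop, sector_map, members, vaf, composition, expression)``.
    All downstream randomness is seeded from ``cfg.rng_seed``.
    """
    pop = simulate_growth(cfg)
    sm, members = sample_honeycomb_sectors(
        pop, sector_radius=sector_radius, pitch=pitch,
        min_cells=min_cells, patient_id=patient_id,
    )
    vaf, comp = sectors_to_bulk(
        pop, sm, members, depth=depth, purity=purity, rng_seed=cfg.rng_seed + 1
    )
    expr = simulate_expression(
        comp, n_genes=n_genes, effect_size=effect_size,
        noise_sd=noise_sd, rng_seed=cfg.rng_seed + 2,
    )
    return pop, sm, members, vaf, comp, expr
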