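"""Core data containers for multi-sector tumor analyses.

A *sector* is a small bulk tissue sample (a few mm across) taken at a known
position on a 2-D tumor slice.  Everything downstream — distances, trees,
spatial statistics — operates on the per-sector containers defined here.

Pairwise dissimilarities are carried in :class:`skbio.DistanceMatrix`
(symmetric, hollow, label-indexed); trees in :class:`skbio.TreeNode`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "SectorMap",
    "MutationMatrix",
    "VafMatrix",
    "ExpressionMatrix",
    "CloneComposition",
    "CNProfile",
    "DistanceMatrix",
    "TreeNode",
    "FormatError",
]


class FormatError(ValueError):
    """An input file or table violates the expected format or an invariant."""


@dataclass(frozen=True)
class SectorMap:
    """Sector identities and their physical (x, y) coordinates in millimetres.

    Parameters
    ----------
    patient_id : str
        Label for the tumor this slice belongs to.
    sectors : list of str
        Ordered, unique sector identifiers.
    coords : ndarray of shape (n_sectors, 2)
        Per-sector (x, y) positions in mm on the slice plane.
    """

    patient_id: str
    sectors: tuple[str, ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        sectors = tuple(str(s) for s in self.sectors)
        coords = np.asarray(self.coords, dtype=float)
        if len(sectors) < 2:
            raise FormatError("a sector map needs at least 2 sectors")
        if len(set(sectors)) != len(sectors):
            dup = sorted({s for s in sectors if sectors.count(s) > 1})
            raise FormatError(f"duplicate sector ids: {dup}")
        if coords.shape != (len(sectors), 2):
            raise FormatError(
                f"coords must be (n, 2); got {coords.shape} for {len(sectors)} sectors"
            )
        if not np.all(np.isfinite(coords)):
            raise FormatError("sector coordinates must be finite")
        coords.flags.writeable = False
        object.__setattr__(self, "sectors", sectors)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.sectors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sector": self.sectors, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )


def _check_labels(values: np.ndarray, rows, cols, rows_what: str, cols_what: str):
    rows = tuple(str(r) for r in rows)
    cols = tuple(str(c) for c in cols)
    if len(set(rows)) != len(rows):
        raise FormatError(f"duplicate {rows_what} labels")
    if len(set(cols)) != len(cols):
        raise FormatError(f"duplicate {cols_what} labels")
    if values.shape != (len(rows), len(cols)):
        raise FormatError(
            f"matrix shape {values.shape} does not match "
            f"{len(rows)} {rows_what} x {len(cols)} {cols_what}"
        )
    return rows, cols


@dataclass(frozen=True)
class MutationMatrix:
    """Binary presence/absence of somatic variants across sectors.

    ``presence[i, j]`` is 1 if variant ``variants[j]`` was observed in sector
    ``sectors[i]``.  Variant identity follows the chrom:pos:ref:alt
    convention but any unique string is accepted.
    """

    sectors: tuple[str, ...]
    variants: tuple[str, ...]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self):
        presence = np.asarray(self.presence)
        sectors, variants = _check_labels(
            presence, self.sectors, self.variants, "sector", "variant"
        )
        if len(variants) < 1:
            raise FormatError("mutation matrix needs at least one variant")
        uniq = np.unique(presence)
        if not np.isin(uniq, [0, 1]).all():
            raise FormatError(f"presence entries must be 0/1; found {uniq[:5]}")
        presence = presence.astype(np.int8)
        presence.flags.writeable = False
        object.__setattr__(self, "sectors", sectors)
        object.__setattr__(self, "variants", variants)
        object.__setattr__(self, "presence", presence)

    def to_frame(self) -> pd.DataFrame:
        """Variants x sectors table (the on-disk orientation)."""
        return pd.DataFrame(
            self.presence.T, index=list(self.variants), columns=list(self.sectors)
        )

    def mutation_set(self, sector: str) -> frozenset[str]:
        i = self.sectors.index(sector)
        return frozenset(v for v, p in zip(self.variants, self.presence[i]) if p)


@dataclass(frozen=True)
class VafMatrix:
    """Variant allele frequencies (sectors x variants), NaN marks missing.

    A missing cell means no sequencing evidence either way (zero depth), as
    opposed to an observed frequency of 0.
    """

    sectors: tuple[str, ...]
    variants: tuple[str, ...]
    vaf: np.ndarray = field(repr=False)

    def __post_init__(self):
        vaf = np.asarray(self.vaf, dtype=float)
        sectors, variants = _check_labels(
            vaf, self.sectors, self.variants, "sector", "variant"
        )
        if len(variants) < 1:
            raise FormatError("VAF matrix needs at least one variant")
        finite = vaf[~np.isnan(vaf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise FormatError("VAF values must lie in [0, 1]")
        vaf.flags.writeable = False
        object.__setattr__(self, "sectors", sectors)
        object.__setattr__(self, "variants", variants)
        object.__setattr__(self, "vaf", vaf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vaf.T, index=list(self.variants), columns=list(self.sectors)
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression, genes x sectors, nonnegative."""

    genes: tuple[str, ...]
    sectors: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        genes, sectors = _check_labels(values, self.genes, self.sectors, "gene", "sector")
        if not np.all(np.isfinite(values)):
            raise FormatError("expression values must be finite")
        if values.size and values.min() < 0:
            raise FormatError("expression values must be nonnegative")
        values.flags.writeable = False
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "sectors", sectors)
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.genes), columns=list(self.sectors)
        )


@dataclass(frozen=True)
class CloneComposition:
    """Per-sector clone proportions (sectors x clones), rows summing to 1."""

    sectors: tuple[str, ...]
    clones: tuple[str, ...]
    proportions: np.ndarray = field(repr=False)

    def __post_init__(self):
        props = np.asarray(self.proportions, dtype=float)
        sectors, clones = _check_labels(props, self.sectors, self.clones, "sector", "clone")
        if props.size and props.min() < -1e-12:
            raise FormatError("clone proportions must be nonnegative")
        sums = props.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            raise FormatError(
                f"clone proportions must sum to 1 per sector; "
                f"offenders: {[sectors[i] for i in np.flatnonzero(bad)[:5]]}"
            )
        props.flags.writeable = False
        object.__setattr__(self, "sectors", sectors)
        object.__setattr__(self, "clones", clones)
        object.__setattr__(self, "proportions", props)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=list(self.sectors), columns=list(self.clones)
        )


@dataclass(frozen=True)
class CNProfile:
    """Copy-number segments with 0-based half-open coordinates.

    ``segments`` is a list of (chrom, start, end, cn) tuples; ``genome_length``
    is the total base count over which aberrant fractions are reported.
    """

    segments: tuple[tuple[str, int, int, float], ...]
    genome_length: int

    def __post_init__(self):
        segs = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.segments:
            start, end, cn = int(start), int(end), float(cn)
            if end <= start:
                raise FormatError(f"segment {chrom}:{start}-{end} has end <= start")
            if cn < 0:
                raise FormatError("copy number must be >= 0")
            by_chrom.setdefault(str(chrom), []).append((start, end))
            segs.append((str(chrom), start, end, cn))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise FormatError(f"overlapping segments on {chrom} at {s2}")
        if self.genome_length <= 0:
            raise FormatError("genome_length must be positive")
        total = sum(e - s for _, s, e, _ in segs)
        if total > self.genome_length:
            raise FormatError("segments cover more bases than genome_length")
        object.__setattr__(self, "segments", tuple(segs))
        object.__setattr__(self, "genome_length", int(self.genome_length))
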