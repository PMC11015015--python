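"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are UTF-8 TSV with a header row and '.' decimals.
Mutation input may also be a minimal multi-sample VCF (CHROM/POS/REF/ALT
plus a per-sample AD field), parsed with pysam; trees are newick.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam
from skbio import TreeNode

from .model import (
    CloneComposition,
    CNProfile,
    ExpressionMatrix,
    FormatError,
    MutationMatrix,
    SectorMap,
    VafMatrix,
)

__all__ = [
    "read_sector_map",
    "write_sector_map",
    "read_mutation_input",
    "write_vaf_matrix",
    "write_mutation_matrix",
    "binarize_and_filter",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clone_composition",
    "write_clone_composition",
    "read_cn_profile",
    "read_tree",
    "write_tree",
]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap into a format error with the path
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc


def _numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in {path}: {exc}") from exc


def read_sector_map(path, patient_id: str | None = None) -> SectorMap:
    """Read a sector coordinate table (columns: sector, x, y; mm).

    File order is preserved.  ``patient_id`` defaults to the file stem.
    """
    df = _read_tsv(path)
    for col in ("sector", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if patient_id is None:
        patient_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    coords = _numeric(df[["x", "y"]], path).to_numpy()
    return SectorMap(patient_id, tuple(df["sector"]), coords)


def write_sector_map(sm: SectorMap, path) -> None:
    sm.to_frame().to_csv(path, sep="\t", index=False)


def _vaf_from_vcf(path) -> VafMatrix:
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample columns")
        variants, rows = [], []
        for rec in vcf:
            for alt in rec.alts or ("?",):
                variants.append(f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}")
                row = []
                for s in samples:
                    ad = rec.samples[s].get("AD")
                    if ad is None or any(a is None for a in ad):
                        row.append(np.nan)
                        continue
                    ref_d, alt_d = int(ad[0]), int(ad[1])
                    depth = ref_d + alt_d
                    row.append(alt_d / depth if depth > 0 else np.nan)
                rows.append(row)
    if not variants:
        raise FormatError(f"{path}: VCF contains no variant records")
    vaf = np.asarray(rows, dtype=float).T  # sectors x variants
    return VafMatrix(tuple(samples), tuple(variants), vaf)


def read_mutation_input(path, format: str = "tsv") -> VafMatrix | MutationMatrix:
    """Read per-sector variant data.

    ``format="tsv"`` expects a variants x sectors numeric table; a table of
    pure 0/1 entries is returned as a :class:`MutationMatrix`, anything else
    as a :class:`VafMatrix`.  ``format="vcf"`` parses a minimal multi-sample
    VCF; the VAF of each call is alt_depth/(ref_depth+alt_depth), with
    zero-depth cells marked missing (NaN), never coerced to 0.
    """
    if format == "vcf":
        return _vaf_from_vcf(path)
    if format != "tsv":
        raise FormatError(f"unknown mutation input format: {format!r}")
    df = _read_tsv(path)
    first = df.columns[0]
    df = df.set_index(first)
    values = _numeric(df, path).to_numpy().T  # file is variants x sectors
    sectors, variants = tuple(df.columns), tuple(df.index)
    finite = values[~np.isnan(values)]
    if np.isin(finite, [0.0, 1.0]).all() and not np.isnan(values).any():
        return MutationMatrix(sectors, variants, values.astype(np.int8))
    return VafMatrix(sectors, variants, values)


def write_vaf_matrix(v: VafMatrix, path) -> None:
    v.to_frame().to_csv(path, sep="\t", index_label="variant")


def write_mutation_matrix(m: MutationMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="variant")


def binarize_and_filter(
    v: VafMatrix,
    present_threshold: float = 0.0,
    min_max_vaf: float = 0.05,
    snv_only: bool = False,
) -> MutationMatrix:
    """Call variant presence from VAFs with a detectability filter.

    A variant is kept only if its maximum VAF over sectors exceeds
    ``min_max_vaf`` (the false-positive guard: a mutation must be clearly
    observed somewhere).  Kept variants are scored present in a sector when
    VAF > ``present_threshold``.  Missing cells count as 0 for both steps; a
    variant missing in every sector is dropped.  ``snv_only`` restricts to
    chrom:pos:ref:alt variants whose ref and alt are single bases.
    """
    if not (0 <= present_threshold <= 1) or not (0 <= min_max_vaf <= 1):
        raise FormatError("thresholds must lie in [0, 1]")
    vaf = np.nan_to_num(v.vaf, nan=0.0)
    all_missing = np.isnan(v.vaf).all(axis=0)
    keep = (vaf.max(axis=0) > min_max_vaf) & ~all_missing
    if snv_only:
        def is_snv(vid: str) -> bool:
            parts = vid.split(":")
            return len(parts) == 4 and len(parts[2]) == 1 and len(parts[3]) == 1
        keep &= np.array([is_snv(vid) for vid in v.variants])
    if not keep.any():
        raise FormatError(
            "no variant survives filtering "
            f"(min_max_vaf={min_max_vaf}, snv_only={snv_only})"
        )
    presence = (vaf[:, keep] > present_threshold).astype(np.int8)
    variants = tuple(np.asarray(v.variants, dtype=object)[keep])
    return MutationMatrix(v.sectors, variants, presence)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x sectors normalized expression TSV (first column = gene)."""
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    values = _numeric(df, path).to_numpy()
    return ExpressionMatrix(tuple(df.index), tuple(df.columns), values)


def write_expression_matrix(e: ExpressionMatrix, path) -> None:
    e.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_clone_composition(path) -> CloneComposition:
    """Read a sectors x clones proportion TSV (first column = sector)."""
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    props = _numeric(df, path).to_numpy()
    return CloneComposition(tuple(df.index), tuple(df.columns), props)


def write_clone_composition(c: CloneComposition, path) -> None:
    c.to_frame().to_csv(path, sep="\t", index_label="sector")


def read_cn_profile(path, genome_length: int | None = None) -> CNProfile:
    """Read a copy-number segment TSV (chrom, start, end, cn; 0-based half-open).

    ``genome_length`` defaults to the total length of the listed segments.
    """
    df = _read_tsv(path)
    for col in ("chrom", "start", "end", "cn"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    segments = [
        (row.chrom, int(row.start), int(row.end), float(row.cn))
        for row in df.itertuples()
    ]
    if genome_length is None:
        genome_length = sum(e - s for _, s, e, _ in segments)
    return CNProfile(tuple(segments), genome_length)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(os.fspath(path), format="newick")
    if tree.count(tips=True) < 2:
        raise FormatError(f"{path}: tree has fewer than 2 leaves")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(os.fspath(path), format="newick")
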