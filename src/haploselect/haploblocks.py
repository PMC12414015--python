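"""LD-based haplotype blocks and per-block haplotype values.

Blocks are runs of contiguous markers in strong linkage disequilibrium.
LD is measured as the squared Pearson correlation of major-allele dosages
across the panel (for inbred lines this coincides with haplotype r^2 and
needs no phasing).  Within each chromosome a greedy left-to-right scan
extends the open block to the next marker when either the adjacent pair or
the pair (block's left boundary, next marker) reaches the threshold;
markers in weak LD become singleton blocks, so the blocks always partition
the map.

The value of a haplotype copy at a block is the sum of its markers'
additive effects; identical allele strings within a block share a variant
identity (and hence a value).  These per-copy block values are the inputs
to every group-fitness function.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import EffectsTable, HaplotypePanel, dosage_matrix
from .errors import FormatError, ParameterError, UndefinedLDError

__all__ = [
    "HaploBlock",
    "BlockValueTensor",
    "pairwise_r2",
    "build_blocks",
    "catalog_block_values",
    "write_blocks_bed",
    "write_block_values",
]


@dataclass(frozen=True)
class HaploBlock:
    """Contiguous run of markers on one chromosome, 0-based half-open range."""

    block_id: int
    chrom: str
    start: int  # first marker index (inclusive)
    stop: int  # last marker index (exclusive)

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise FormatError("empty block")

    @property
    def marker_indices(self) -> range:
        return range(self.start, self.stop)

    @property
    def n_markers(self) -> int:
        return self.stop - self.start


@dataclass
class BlockValueTensor:
    """Per-block, per-individual, per-copy haplotype values and variant codes.

    ``values[b, n, m]`` is the summed effect of individual n's copy m over
    block b's markers; ``variant_codes[b, n, m]`` is a dense integer label of
    the copy's allele string within block b (equal codes imply equal values).
    """

    values: np.ndarray  # (B, N, 2) float
    variant_codes: np.ndarray  # (B, N, 2) int
    individual_ids: list[str] | None = None
    blocks: list[HaploBlock] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.variant_codes = np.asarray(self.variant_codes, dtype=np.int64)
        if self.values.shape != self.variant_codes.shape or self.values.ndim != 3:
            raise FormatError("values and variant_codes must share shape (B, N, 2)")
        if self.values.shape[2] != 2:
            raise FormatError("copy axis must have length 2")

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    def individual_totals(self) -> np.ndarray:
        """Per-individual sum over blocks and copies (= GEBV minus intercept)."""
        return self.values.sum(axis=(0, 2))


def pairwise_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of dosage columns i and j across individuals."""
    d = dosage_matrix(panel)
    return _r2_from_columns(d[:, i].astype(float), d[:, j].astype(float))


def _r2_from_columns(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise UndefinedLDError("r^2 undefined at a monomorphic locus")
    cov = float(np.mean((a - a.mean()) * (b - b.mean())))
    return cov * cov / (va * vb)


def build_blocks(panel: HaplotypePanel, r2_threshold: float = 0.5) -> list[HaploBlock]:
    """Greedy LD chaining into blocks; partition of all markers per chromosome.

    The open block [s, i] is extended to marker i+1 when r^2(i, i+1) or
    r^2(s, i+1) reaches ``r2_threshold``; monomorphic pairs count as below
    threshold.  Otherwise the block closes and i+1 opens a new one.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ParameterError("r2_threshold must be in (0, 1]")
    d = dosage_matrix(panel).astype(float)
    dc = d - d.mean(axis=0, keepdims=True)
    var = dc.var(axis=0)

    def linked(a: int, b: int) -> bool:
        if var[a] == 0.0 or var[b] == 0.0:
            return False
        cov = float(np.mean(dc[:, a] * dc[:, b]))
        return cov * cov / (var[a] * var[b]) >= r2_threshold

    blocks: list[HaploBlock] = []
    for chrom, sl in panel.map.chrom_slices().items():
        start = sl.start
        for i in range(sl.start, sl.stop - 1):
            if linked(i, i + 1) or linked(start, i + 1):
                continue
            blocks.append(HaploBlock(len(blocks), chrom, start, i + 1))
            start = i + 1
        blocks.append(HaploBlock(len(blocks), chrom, start, sl.stop))
    return blocks


def catalog_block_values(
    panel: HaplotypePanel, blocks: list[HaploBlock], effects: EffectsTable
) -> BlockValueTensor:
    """Sum desirability-oriented marker effects over each block per haplotype copy."""
    effects.check_alignment(panel)
    n = panel.n_individuals
    b = len(blocks)
    covered = sorted(idx for blk in blocks for idx in blk.marker_indices)
    if covered != list(range(panel.n_markers)):
        raise FormatError("blocks must partition the panel's markers")
    values = np.zeros((b, n, 2))
    codes = np.zeros((b, n, 2), dtype=np.int64)
    for bi, blk in enumerate(blocks):
        seg = panel.alleles[:, :, blk.start : blk.stop]  # (N, 2, L)
        values[bi] = seg.astype(float) @ effects.effect[blk.start : blk.stop]
        flat = seg.reshape(n * 2, blk.n_markers)
        _, inv = np.unique(flat, axis=0, return_inverse=True)
        codes[bi] = inv.reshape(n, 2)
    return BlockValueTensor(values, codes, list(panel.individual_ids), list(blocks))


def write_blocks_bed(blocks: list[HaploBlock], panel: HaplotypePanel,
                     path: str | Path) -> None:
    """BED-like TSV: chrom, start_bp, end_bp, block_id, n_markers."""
    rows = [
        (blk.chrom, int(panel.map.pos_bp[blk.start]),
         int(panel.map.pos_bp[blk.stop - 1]), blk.block_id, blk.n_markers)
        for blk in blocks
    ]
    pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "block_id",
                                "n_markers"]).to_csv(path, sep="\t", index=False)


def write_block_values(tensor: BlockValueTensor, path: str | Path) -> None:
    """Long-format TSV: block_id, individual_id, copy, variant_id, value."""
    b, n, _ = tensor.values.shape
    ids = tensor.individual_ids or [f"ind{i + 1}" for i in range(n)]
    rows = []
    for bi in range(b):
        for ni in range(n):
            for m in (0, 1):
                rows.append((bi, ids[ni], m + 1,
                             int(tensor.variant_codes[bi, ni, m]),
                             tensor.values[bi, ni, m]))
    pd.DataFrame(rows, columns=["block_id", "individual_id", "copy",
                                "variant_id", "value"]).to_csv(
        path, sep="\t", index=False)


def read_block_values(path: str | Path) -> BlockValueTensor:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    block_ids = np.sort(df["block_id"].unique())
    ids = list(dict.fromkeys(df["individual_id"]))
    b, n = len(block_ids), len(ids)
    values = np.zeros((b, n, 2))
    codes = np.zeros((b, n, 2), dtype=np.int64)
    pos = {ind: i for i, ind in enumerate(ids)}
    bpos = {int(bid): i for i, bid in enumerate(block_ids)}
    for row in df.itertuples(index=False):
        values[bpos[int(row.block_id)], pos[row.individual_id], int(row.copy) - 1] = row.value
        codes[bpos[int(row.block_id)], pos[row.individual_id], int(row.copy) - 1] = row.variant_id
    return BlockValueTensor(values, codes, ids)
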