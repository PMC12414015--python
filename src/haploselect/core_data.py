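"""Data model and I/O for genotypes, marker maps, phenotypes and marker effects.

The central container is :class:`HaplotypePanel`: an N x 2 x M binary allele
array (individuals x haplotype copies x markers) over a physically ordered
:class:`MarkerMap`.  Alleles are recoded at read time so that ``1`` always
denotes the per-locus major allele (frequency >= 0.5 across all copies; a
50/50 tie keeps the input's allele-1 coding).  Base-pair positions are
1-based as in VCF; all in-memory marker indexing is 0-based.

Panels of inbred lines (selfing crops) may be supplied as dosage rows under
``assume_inbred=True``, which maps homozygous dosages 0/2 onto identical
haplotype copies and rejects dosage 1.  Missing genotypes are rejected:
imputation is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    InbreedingViolationError,
    MissingGenotypeError,
    PhaseError,
)

__all__ = [
    "MarkerMap",
    "HaplotypePanel",
    "PhenotypeTable",
    "EffectsTable",
    "read_marker_map",
    "write_marker_map",
    "read_haplotype_panel",
    "write_haplotype_panel",
    "dosage_matrix",
    "read_effects",
    "write_effects",
    "read_phenotypes",
    "write_phenotypes",
    "write_panel_vcf",
]


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map: id, chromosome, bp position, optional cM position."""

    marker_id: np.ndarray  # str, length M
    chrom: np.ndarray  # str, length M
    pos_bp: np.ndarray  # int, length M, 1-based
    pos_cm: np.ndarray | None = None  # float, length M, optional

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos_bp", np.asarray(self.pos_bp, dtype=np.int64))
        if self.pos_cm is not None:
            object.__setattr__(self, "pos_cm", np.asarray(self.pos_cm, dtype=float))
        m = len(self.marker_id)
        if not (len(self.chrom) == len(self.pos_bp) == m):
            raise FormatError("marker map columns have unequal lengths")
        if self.pos_cm is not None and len(self.pos_cm) != m:
            raise FormatError("pos_cm length mismatch")
        if len(set(self.marker_id)) != m:
            raise FormatError("duplicate marker_ids in map")
        if np.any(self.pos_bp < 0):
            raise FormatError("negative bp position")
        for _, idx in self.chrom_slices().items():
            bp = self.pos_bp[idx]
            if np.any(np.diff(bp) <= 0):
                raise FormatError("pos_bp not strictly increasing within chromosome")
            if self.pos_cm is not None and np.any(np.diff(self.pos_cm[idx]) < 0):
                raise FormatError("pos_cm decreasing within chromosome")

    def __len__(self) -> int:
        return len(self.marker_id)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in order of first appearance."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                name = str(chroms[start])
                if name in out:
                    raise FormatError(f"chromosome {name!r} not contiguous in map")
                out[name] = slice(start, i)
                start = i
        return out

    def genetic_positions(self, cm_per_mb: float = 1.0) -> np.ndarray:
        """cM positions: ``pos_cm`` when present, else ``pos_bp`` * cm_per_mb / 1e6."""
        if self.pos_cm is not None:
            return self.pos_cm.copy()
        return self.pos_bp.astype(float) * cm_per_mb / 1e6


@dataclass
class HaplotypePanel:
    """Binary allele matrix (N individuals x 2 copies x M markers) plus map.

    Entry 1 means the individual carries the per-locus major allele on that
    haplotype copy.
    """

    individual_ids: list[str]
    alleles: np.ndarray  # (N, 2, M) uint8 in {0, 1}
    map: MarkerMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise FormatError("alleles must have shape (N, 2, M)")
        n, _, m = self.alleles.shape
        if n < 1 or m < 1:
            raise FormatError("panel needs at least one individual and one marker")
        if len(self.individual_ids) != n:
            raise FormatError("individual_ids length mismatch")
        if len(set(self.individual_ids)) != n:
            raise FormatError("duplicate individual_ids")
        if len(self.map) != m:
            raise AlignmentError("map length does not match marker axis")
        if self.alleles.max(initial=0) > 1:
            raise FormatError("allele entries must be 0/1")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[2]

    def major_allele_freq(self) -> np.ndarray:
        """Per-locus frequency of allele 1 across all 2N copies."""
        return self.alleles.mean(axis=(0, 1))

    def dosages(self) -> np.ndarray:
        return dosage_matrix(self)

    def subset(self, indices: Sequence[int]) -> "HaplotypePanel":
        idx = list(indices)
        return HaplotypePanel(
            [self.individual_ids[i] for i in idx], self.alleles[idx], self.map
        )


@dataclass
class PhenotypeTable:
    """Replicated trait scores: one row per (individual, replicate)."""

    data: pd.DataFrame  # columns: individual_id, replicate, score

    def __post_init__(self) -> None:
        required = {"individual_id", "replicate", "score"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"phenotype table needs columns {sorted(required)}")
        if len(self.data) == 0:
            raise FormatError("empty phenotype table")
        if (self.data["replicate"] < 1).any():
            raise FormatError("replicate numbers must be >= 1")
        if self.data["score"].isna().any():
            raise FormatError("missing scores not allowed")

    def validate_against(self, panel: HaplotypePanel) -> None:
        unknown = set(self.data["individual_id"]) - set(panel.individual_ids)
        if unknown:
            raise AlignmentError(f"phenotyped individuals not in panel: {sorted(unknown)[:5]}")


@dataclass
class EffectsTable:
    """Additive effect of the major allele at each locus, plus an intercept."""

    intercept: float
    effect: np.ndarray  # length M
    marker_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.effect = np.asarray(self.effect, dtype=float)
        if self.effect.ndim != 1:
            raise FormatError("effect must be a 1-D vector")
        if not np.isfinite(self.effect).all() or not np.isfinite(self.intercept):
            raise FormatError("effects and intercept must be finite")
        if self.marker_ids is not None:
            self.marker_ids = np.asarray(self.marker_ids, dtype=object)
            if len(self.marker_ids) != len(self.effect):
                raise AlignmentError("marker_ids length mismatch")

    def check_alignment(self, panel: HaplotypePanel) -> None:
        if len(self.effect) != panel.n_markers:
            raise AlignmentError(
                f"{len(self.effect)} effects vs {panel.n_markers} panel markers"
            )
        if self.marker_ids is not None and not np.array_equal(
            self.marker_ids, panel.map.marker_id
        ):
            raise AlignmentError("marker_id order differs between effects and panel")


# ---------------------------------------------------------------------------
# marker map I/O


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    for col in ("marker_id", "chrom", "pos_bp"):
        if col not in df.columns:
            raise FormatError(f"marker map missing column {col!r}")
    pos_cm = df["pos_cm"].to_numpy(float) if "pos_cm" in df.columns else None
    return MarkerMap(
        df["marker_id"].to_numpy(object),
        df["chrom"].to_numpy(object),
        df["pos_bp"].to_numpy(np.int64),
        pos_cm,
    )


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    cols = {"marker_id": mmap.marker_id, "chrom": mmap.chrom, "pos_bp": mmap.pos_bp}
    if mmap.pos_cm is not None:
        cols["pos_cm"] = mmap.pos_cm
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel I/O


def _recode_major(alleles: np.ndarray) -> np.ndarray:
    """Flip loci so allele 1 is the major allele; ties keep the input coding."""
    freq = alleles.mean(axis=(0, 1))
    flip = freq < 0.5
    out = alleles.copy()
    out[:, :, flip] = 1 - out[:, :, flip]
    return out


def _read_panel_vcf(path: str | Path, assume_inbred: bool) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    marker_id, chrom, pos = [], [], []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"multi-allelic site at {var.CHROM}:{var.POS}")
        gts = var.genotypes  # list of [a1, a2, phased]
        col = np.empty((len(ids), 2), dtype=np.int16)
        for i, (a1, a2, phased) in enumerate(gts):
            if a1 < 0 or a2 < 0:
                raise MissingGenotypeError(
                    f"missing genotype for {ids[i]} at {var.CHROM}:{var.POS}"
                )
            if a1 != a2:
                if assume_inbred:
                    raise InbreedingViolationError(
                        f"heterozygote for {ids[i]} at {var.CHROM}:{var.POS} "
                        "under assume_inbred"
                    )
                if not phased:
                    raise PhaseError(
                        f"unphased heterozygote for {ids[i]} at {var.CHROM}:{var.POS}"
                    )
            col[i, 0], col[i, 1] = a1, a2
        columns.append(col)
        marker_id.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
    if not columns:
        raise FormatError("VCF contains no variants")
    # ALT carries allele code 1; at a 50/50 tie the recode keeps that coding.
    alleles = np.stack(columns, axis=2).astype(np.uint8)
    mmap = MarkerMap(np.array(marker_id, object), np.array(chrom, object), np.array(pos))
    return HaplotypePanel(ids, _recode_major(alleles), mmap)


def _read_panel_tsv(
    path: str | Path, mmap: MarkerMap, assume_inbred: bool
) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise FormatError("panel TSV missing 'individual_id' column")
    has_copy = "copy" in df.columns
    marker_cols = [c for c in df.columns if c not in ("individual_id", "copy")]
    if list(marker_cols) != list(mmap.marker_id):
        raise AlignmentError("panel TSV marker columns do not match map")
    vals = df[marker_cols].to_numpy()
    if np.isnan(vals.astype(float)).any():
        raise MissingGenotypeError("missing genotype values in panel TSV")
    vals = vals.astype(np.int64)
    if has_copy:
        ids = list(dict.fromkeys(df["individual_id"]))
        n, m = len(ids), len(marker_cols)
        alleles = np.zeros((n, 2, m), dtype=np.uint8)
        seen = set()
        for _, row in df.iterrows():
            c = int(row["copy"])
            if c not in (1, 2):
                raise FormatError("copy column must be 1 or 2")
            key = (row["individual_id"], c)
            if key in seen:
                raise FormatError(f"duplicate row for {key}")
            seen.add(key)
        for i, ind in enumerate(ids):
            sub = df[df["individual_id"] == ind]
            if len(sub) != 2:
                raise FormatError(f"individual {ind} needs exactly 2 copy rows")
            for _, row in sub.iterrows():
                alleles[i, int(row["copy"]) - 1] = (
                    row[marker_cols].to_numpy(np.int64).astype(np.uint8)
                )
        if vals.max(initial=0) > 1 or vals.min(initial=0) < 0:
            raise FormatError("haplotype rows must be 0/1")
    else:
        if not assume_inbred:
            raise PhaseError(
                "dosage rows require assume_inbred=True (phase is unknown)"
            )
        if ((vals != 0) & (vals != 2)).any():
            bad = vals[(vals != 0) & (vals != 2)]
            if (bad == 1).any():
                raise InbreedingViolationError(
                    "dosage 1 (heterozygote) under assume_inbred"
                )
            raise FormatError("dosage values must be 0/1/2")
        ids = list(df["individual_id"])
        alleles = np.repeat((vals // 2).astype(np.uint8)[:, None, :], 2, axis=1)
    return HaplotypePanel(ids, _recode_major(alleles), mmap)


def read_haplotype_panel(
    path: str | Path,
    format: str = "vcf",
    assume_inbred: bool = False,
    map_path: str | Path | None = None,
    marker_map: MarkerMap | None = None,
) -> HaplotypePanel:
    """Read a panel from a phased VCF or a TSV haplotype/dosage matrix.

    TSV panels need a companion marker map (``map_path`` or ``marker_map``)
    because the matrix itself carries only marker names.
    """
    if format == "vcf":
        return _read_panel_vcf(path, assume_inbred)
    if format == "tsv":
        if marker_map is None:
            if map_path is None:
                raise FormatError("TSV panel requires map_path or marker_map")
            marker_map = read_marker_map(map_path)
        return _read_panel_tsv(path, marker_map, assume_inbred)
    raise FormatError(f"unknown panel format {format!r}")


def write_haplotype_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Write one row per individual-copy pair, columns = marker ids."""
    rows = []
    for i, ind in enumerate(panel.individual_ids):
        for c in (1, 2):
            rows.append([ind, c] + list(panel.alleles[i, c - 1].astype(int)))
    df = pd.DataFrame(rows, columns=["individual_id", "copy"] + list(panel.map.marker_id))
    df.to_csv(path, sep="\t", index=False)


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a phased, uncompressed VCF (alleles coded A=0, B=1)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "haploselect")
    for chrom, sl in panel.map.chrom_slices().items():
        length = int(panel.map.pos_bp[sl].max()) + 1
        header.contigs.add(chrom, length=length)
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                         ("Description", "Genotype")]
    )
    for ind in panel.individual_ids:
        header.add_sample(ind)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(panel.n_markers):
            rec = out.new_record(
                contig=str(panel.map.chrom[j]),
                start=int(panel.map.pos_bp[j]) - 1,
                stop=int(panel.map.pos_bp[j]),
                alleles=("A", "B"),
                id=str(panel.map.marker_id[j]),
            )
            for i, ind in enumerate(panel.individual_ids):
                rec.samples[ind]["GT"] = tuple(int(a) for a in panel.alleles[i, :, j])
                rec.samples[ind].phased = True
            out.write(rec)


def dosage_matrix(panel: HaplotypePanel) -> np.ndarray:
    """N x M major-allele dosage matrix (sum over the two copies; 0/1/2)."""
    return panel.alleles.sum(axis=1, dtype=np.int64)


# ---------------------------------------------------------------------------
# effects I/O


def write_effects(effects: EffectsTable, path: str | Path) -> None:
    """TSV with one row per marker; the header comment carries the intercept."""
    with open(path, "w") as fh:
        fh.write(f"#intercept={float(effects.intercept)!r}\n")
        fh.write("marker_id\teffect\n")
        ids = (
            effects.marker_ids
            if effects.marker_ids is not None
            else [f"m{i}" for i in range(len(effects.effect))]
        )
        for mid, e in zip(ids, effects.effect):
            fh.write(f"{mid}\t{float(e)!r}\n")


def read_effects(path: str | Path, panel: HaplotypePanel | None = None) -> EffectsTable:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#intercept="):
            raise FormatError("effects TSV must start with '#intercept=' line")
        intercept = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", dtype={"marker_id": str})
    if "marker_id" not in df.columns or "effect" not in df.columns:
        raise FormatError("effects TSV needs marker_id and effect columns")
    if df["effect"].isna().any() or len(df) == 0:
        raise FormatError("empty or missing effect values")
    table = EffectsTable(intercept, df["effect"].to_numpy(float),
                         df["marker_id"].to_numpy(object))
    if panel is not None:
        table.check_alignment(panel)
    return table


# ---------------------------------------------------------------------------
# phenotype I/O


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    return PhenotypeTable(df[["individual_id", "replicate", "score"]])


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False)
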