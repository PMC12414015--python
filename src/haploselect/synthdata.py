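"""Seeded generators for synthetic panels, effects, phenotypes and fixtures.

The generator emulates the kind of data the selection machinery is built
for: a panel of fully inbred diploid lines with block-structured linkage
disequilibrium, an additive polygenic trait, and replicated ordinal-like
trial scores on a 1-9 severity scale.  LD is planted directly — each
chromosome is tiled with blocks, and within a block every individual draws
its (identical, inbred) haplotype from a small ancestral pool,
independently across blocks — so within-block r^2 is high by construction
and between-block r^2 is only sampling noise.  This is exactly
controllable and sufficient to exercise block construction, block values,
group fitness and the optimizers; it does not model recombination
gradients, selfing history, or genotyping error.

``heritability`` is specified on the genotype-mean (entry-mean) basis for
the configured replicate count: the residual plot variance is set to
``replicates * var(g) * (1 - h2) / h2`` so that a trial analysed with the
package's own one-way estimator targets h2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import EffectsTable, HaplotypePanel, MarkerMap, PhenotypeTable
from .errors import ParameterError
from .haploblocks import BlockValueTensor

__all__ = [
    "PanelSimSpec",
    "simulate_panel",
    "simulate_effects_phenotypes",
    "make_fixture_f1",
    "random_block_tensor",
    "F1_EXPECTED",
]


@dataclass(frozen=True)
class PanelSimSpec:
    """Dimensions and trait model of a synthetic inbred panel."""

    n_individuals: int = 200
    n_chromosomes: int = 3
    markers_per_chrom: int = 50
    block_length: int = 5  # markers per planted LD block
    n_ancestral_haplotypes: int = 2  # per block; >= 2 keeps markers polymorphic
    h2: float = 0.8  # entry-mean heritability given `replicates`
    trait_min: float = 1.0
    trait_max: float = 9.0
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_length < 1:
            raise ParameterError("block_length must be >= 1")
        if self.n_ancestral_haplotypes < 1:
            raise ParameterError("need >= 1 ancestral haplotype")
        if not (0 < self.h2 <= 1):
            raise ParameterError("h2 must lie in (0, 1]")
        if self.markers_per_chrom % self.block_length:
            raise ParameterError("markers_per_chrom must be a multiple of block_length")


def simulate_panel(spec: PanelSimSpec) -> HaplotypePanel:
    """Inbred panel with planted LD blocks.

    With a 2-haplotype pool the ancestors are complementary (all-0 vs
    all-1), so every within-block marker pair has r^2 = 1 whenever both
    ancestors are present.  Larger pools are random 0/1 haplotypes, nudged
    so no pooled marker is monomorphic by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    m = spec.n_chromosomes * spec.markers_per_chrom
    blocks_per_chrom = spec.markers_per_chrom // spec.block_length
    haplo = np.zeros((n, m), dtype=np.uint8)
    col = 0
    for _ in range(spec.n_chromosomes):
        for _ in range(blocks_per_chrom):
            pool = _ancestral_pool(spec.n_ancestral_haplotypes, spec.block_length, rng)
            picks = rng.integers(0, len(pool), size=n)
            haplo[:, col : col + spec.block_length] = pool[picks]
            col += spec.block_length
    alleles = np.repeat(haplo[:, None, :], 2, axis=1)  # inbred: identical copies
    ids = [f"line{i + 1:04d}" for i in range(n)]
    marker_id = np.array([f"snp{j + 1:05d}" for j in range(m)], dtype=object)
    chrom = np.array(
        [f"chr{c + 1}" for c in range(spec.n_chromosomes)
         for _ in range(spec.markers_per_chrom)],
        dtype=object,
    )
    # evenly spaced at 1 Mb so the default 1 cM/Mb gives ~0.5 M chromosomes
    pos = np.array(
        [1_000_000 * (j + 1) for _ in range(spec.n_chromosomes)
         for j in range(spec.markers_per_chrom)],
        dtype=np.int64,
    )
    return HaplotypePanel(ids, alleles, MarkerMap(marker_id, chrom, pos))


def _ancestral_pool(n_anc: int, length: int, rng: np.random.Generator) -> np.ndarray:
    if n_anc == 1:
        return np.zeros((1, length), dtype=np.uint8)
    if n_anc == 2:
        return np.stack([np.zeros(length, np.uint8), np.ones(length, np.uint8)])
    pool = rng.integers(0, 2, size=(n_anc, length)).astype(np.uint8)
    mono = pool.min(axis=0) == pool.max(axis=0)
    pool[0, mono] = 1 - pool[0, mono]
    return pool


def simulate_effects_phenotypes(
    panel: HaplotypePanel, spec: PanelSimSpec
) -> tuple[EffectsTable, PhenotypeTable, dict]:
    """Additive effects, replicated 1-9 scores, and the ground truth.

    Marker effects are centred Gaussian; plot residual variance is set from
    the entry-mean h2 (see module docstring); scores are an affine rescale
    of genetic value + noise into [trait_min, trait_max], clipped.  The
    returned truth dict carries the effects and true values on the rescaled
    score scale for recovery tests.
    """
    rng = np.random.default_rng(spec.seed + 1)
    d = panel.dosages().astype(float)
    u = rng.normal(0.0, 1.0, size=panel.n_markers)
    g = d @ u
    var_g = float(np.var(g))
    if var_g == 0.0 and spec.h2 > 0:
        raise ParameterError("panel is monomorphic: no genetic variance at h2 > 0")
    if spec.h2 == 1.0:
        sigma2_e = 0.0
    else:
        sigma2_e = spec.replicates * var_g * (1.0 - spec.h2) / spec.h2
    noise = rng.normal(0.0, np.sqrt(sigma2_e) if sigma2_e > 0 else 0.0,
                       size=(spec.replicates, panel.n_individuals))
    raw = g[None, :] + noise  # (r, N)
    lo, hi = float(raw.min()), float(raw.max())
    scale = (spec.trait_max - spec.trait_min) / (hi - lo) if hi > lo else 1.0
    offset = spec.trait_min - lo * scale
    scores = np.clip(raw * scale + offset, spec.trait_min, spec.trait_max)
    rows = [
        {"individual_id": ind, "replicate": r + 1, "score": scores[r, i]}
        for r in range(spec.replicates)
        for i, ind in enumerate(panel.individual_ids)
    ]
    pheno = PhenotypeTable(pd.DataFrame(rows))
    effects = EffectsTable(offset, u * scale, panel.map.marker_id.copy())
    truth = {
        "true_effects": u * scale,
        "true_values": g * scale + offset,
        "h2": spec.h2,
        "sigma2_e_score_scale": sigma2_e * scale**2,
    }
    return effects, pheno, truth


# ---------------------------------------------------------------------------
# hand-enumerable fixture: 4 individuals x 2 blocks

F1_EXPECTED = {
    "gebv_totals": (10.0, 8.0, 13.0, 6.0),
    "ohs_best_k2": 15.0,
    "ohs_argmax_k2": [(0, 2), (1, 2), (2, 3)],
    "opv_best_k2": 22.0,
    "opv_argmax_k2": [(2, 3)],
}


def make_fixture_f1() -> tuple[BlockValueTensor, dict]:
    """The 4-individual, 2-block worked example with known optima.

    Block 1 variants/values: A=4, B=3, C=1, D=5; block 2: E=2, F=0, G=6.
    Copies: ind1=(A,A),(E,F); ind2=(B,C),(E,E); ind3=(A,B),(G,F);
    ind4=(D,C),(F,F).  Expected results are in :data:`F1_EXPECTED`.
    """
    values = np.array(
        [
            [[4.0, 4.0], [3.0, 1.0], [4.0, 3.0], [5.0, 1.0]],  # block 1
            [[2.0, 0.0], [2.0, 2.0], [6.0, 0.0], [0.0, 0.0]],  # block 2
        ]
    )
    codes = np.array(
        [
            [[0, 0], [1, 2], [0, 1], [3, 2]],  # A,B,C,D -> 0,1,2,3
            [[0, 1], [0, 0], [2, 1], [1, 1]],  # E,F,G -> 0,1,2
        ]
    )
    ids = ["ind1", "ind2", "ind3", "ind4"]
    return BlockValueTensor(values, codes, ids), dict(F1_EXPECTED)


def random_block_tensor(
    n_individuals: int,
    n_blocks: int,
    rng: np.random.Generator,
    max_variants: int = 4,
) -> BlockValueTensor:
    """Random but internally consistent tensor (equal codes => equal values)."""
    codes = rng.integers(0, max_variants, size=(n_blocks, n_individuals, 2))
    variant_values = rng.normal(0.0, 1.0, size=(n_blocks, max_variants))
    values = variant_values[np.arange(n_blocks)[:, None, None], codes]
    return BlockValueTensor(values.astype(float), codes)
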