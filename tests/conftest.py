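import numpy as np
import pandas as pd
import pytest

from haploselect.core_data import (
    EffectsTable,
    HaplotypePanel,
    MarkerMap,
    PhenotypeTable,
)
from haploselect.synthdata import (
    PanelSimSpec,
    make_fixture_f1,
    simulate_effects_phenotypes,
    simulate_panel,
)


@pytest.fixture(scope="session")
def f1():
    """Hand-enumerable 4-individual x 2-block tensor plus expected optima."""
    tensor, expected = make_fixture_f1()
    return tensor, expected


@pytest.fixture()
def tiny_map():
    return MarkerMap(
        np.array(["m1", "m2", "m3"], object),
        np.array(["1A", "1A", "1A"], object),
        np.array([100, 200, 300]),
    )


def make_panel(dosages: np.ndarray, chrom: str = "1A") -> HaplotypePanel:
    """Inbred panel from a 0/2 dosage matrix (helper used across tests)."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    alleles = np.repeat((dosages // 2).astype(np.uint8)[:, None, :], 2, axis=1)
    mmap = MarkerMap(
        np.array([f"m{j + 1}" for j in range(m)], object),
        np.array([chrom] * m, object),
        np.arange(1, m + 1) * 1000,
    )
    return HaplotypePanel([f"i{i + 1}" for i in range(n)], alleles, mmap)


@pytest.fixture(scope="session")
def synthetic_trial():
    """Moderate synthetic panel with planted LD and a replicated trial."""
    spec = PanelSimSpec(
        n_individuals=150, n_chromosomes=3, markers_per_chrom=30,
        block_length=5, h2=0.8, replicates=2, seed=42,
    )
    panel = simulate_panel(spec)
    effects, pheno, truth = simulate_effects_phenotypes(panel, spec)
    return panel, effects, pheno, truth, spec


@pytest.fixture()
def pheno_two_rep():
    return PhenotypeTable(
        pd.DataFrame(
            {
                "individual_id": ["A", "A", "B", "B"],
                "replicate": [1, 2, 1, 2],
                "score": [3.0, 5.0, 5.0, 7.0],
            }
        )
    )
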