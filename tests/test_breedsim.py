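import numpy as np
import pytest

from haploselect.breedsim import (
    SimConfig,
    _GeneticMap,
    expected_heterozygosity,
    genetic_value,
    half_diallel_plan,
    make_dh,
    meiosis_gamete,
    metrics_to_frame,
    run_breeding_simulation,
)
from haploselect.core_data import EffectsTable, MarkerMap
from haploselect.effects import gebv
from haploselect.errors import ParameterError
from haploselect.synthdata import (
    PanelSimSpec,
    simulate_effects_phenotypes,
    simulate_panel,
)


class TestDiallel:
    @pytest.mark.parametrize("n,expected", [(50, 1225), (4, 6), (2, 1)])
    def test_counts(self, n, expected):
        plan = half_diallel_plan(list(range(n)))
        assert len(plan) == expected
        assert all(a < b for a, b in plan)  # no selfs, no reciprocals

    def test_too_few_parents(self):
        with pytest.raises(ParameterError):
            half_diallel_plan(["solo"])


def two_marker_map(distance_cm):
    return MarkerMap(
        np.array(["a", "b"], object), np.array(["1"] * 2, object),
        np.array([1, int(distance_cm * 1e6) + 1]),
    )


class TestMeiosis:
    def test_zero_length_map_co_inherits(self):
        mmap = MarkerMap(np.array(["a", "b"], object), np.array(["1", "1"], object),
                         np.array([1, 2]), pos_cm=np.array([0.0, 0.0]))
        ind = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        with pytest.warns(UserWarning):
            gmap = _GeneticMap(mmap, 1.0)
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(50):
            g = meiosis_gamete(ind, gmap, rng)
            assert g[0] == g[1]  # entire chromosome from one parent haplotype
            seen.add(int(g[0]))
        assert seen == {0, 1}  # both starting phases occur

    def test_haldane_recombination_fraction_50cm(self):
        gmap = _GeneticMap(two_marker_map(50.0), 1.0)
        ind = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        rng = np.random.default_rng(1)
        n = 100_000
        rec = sum(
            g[0] != g[1] for g in (meiosis_gamete(ind, gmap, rng) for _ in range(n))
        )
        p = (1 - np.exp(-1.0)) / 2
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(rec - n * p) < 3 * sigma

    def test_homozygous_parent_gives_identical_gamete(self):
        gmap = _GeneticMap(two_marker_map(50.0), 1.0)
        ind = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        rng = np.random.default_rng(2)
        for _ in range(20):
            assert np.array_equal(meiosis_gamete(ind, gmap, rng), [1, 0])

    def test_dh_exactly_homozygous(self):
        gmap = _GeneticMap(two_marker_map(80.0), 1.0)
        ind = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        rng = np.random.default_rng(3)
        for _ in range(50):
            dh = make_dh(ind, gmap, rng)
            assert np.array_equal(dh[0], dh[1])


class TestValuesAndDiversity:
    def test_genetic_value_matches_gebv(self, synthetic_trial):
        panel, eff, *_ = synthetic_trial
        expected = gebv(panel, eff)
        for i in (0, 3, 7):
            assert genetic_value(panel.alleles[i], eff) == pytest.approx(
                expected.iloc[i]
            )

    def test_zero_effects_give_intercept(self):
        eff = EffectsTable(4.2, np.zeros(3))
        ind = np.array([[1, 0, 1], [0, 0, 1]], dtype=np.uint8)
        assert genetic_value(ind, eff) == pytest.approx(4.2)

    @pytest.mark.parametrize(
        "p,expected", [(0.5, 0.5), (0.25, 0.375), (0.0, 0.0), (1.0, 0.0)]
    )
    def test_expected_heterozygosity_closed_form(self, p, expected):
        n = 4
        copies = np.zeros(2 * n)
        copies[: int(round(p * 2 * n))] = 1
        pop = copies.reshape(n, 2, 1)
        assert expected_heterozygosity(pop) == pytest.approx(expected)


@pytest.fixture(scope="module")
def desk_sim():
    spec = PanelSimSpec(n_individuals=40, n_chromosomes=2, markers_per_chrom=20,
                        block_length=5, h2=0.8, seed=31)
    panel = simulate_panel(spec)
    eff, _, _ = simulate_effects_phenotypes(panel, spec)
    cfg = SimConfig(n_parents=8, dh_per_cross=4, selected_per_cross=2,
                    new_parents_per_cycle=3, retained_parents=5,
                    cycles=8, replicates=3, seed=5)
    reps = run_breeding_simulation(panel, eff, panel.individual_ids[:8], cfg)
    return panel, eff, cfg, reps


class TestSimulation:
    def test_config_validation(self):
        with pytest.raises(ParameterError):
            SimConfig(n_parents=10, new_parents_per_cycle=3, retained_parents=5)
        with pytest.raises(ParameterError):
            SimConfig(n_parents=10, dh_per_cross=2, selected_per_cross=5,
                      new_parents_per_cycle=5, retained_parents=5)

    def test_unknown_founder_rejected(self, desk_sim):
        panel, eff, cfg, _ = desk_sim
        with pytest.raises(KeyError):
            run_breeding_simulation(panel, eff, ["ghost"] * cfg.n_parents, cfg)

    def test_metrics_shape_and_bounds(self, desk_sim):
        _, _, cfg, reps = desk_sim
        assert len(reps) == cfg.replicates
        frame = metrics_to_frame(reps)
        assert len(frame) == cfg.replicates * cfg.cycles
        assert (frame["genetic_variance"] >= 0).all()
        assert frame["expected_heterozygosity"].between(0, 0.5).all()

    def test_selection_improves_trait(self, desk_sim):
        _, _, _, reps = desk_sim
        # lower genetic value = better; final parents beat the founders
        for rep in reps:
            assert rep[-1].mean_genetic_value < rep[0].mean_genetic_value

    def test_diversity_declines(self, desk_sim):
        _, _, _, reps = desk_sim
        declines = sum(
            rep[-1].expected_heterozygosity < rep[0].expected_heterozygosity
            for rep in reps
        )
        assert declines == len(reps)

    def test_null_effects_give_constant_mean(self, desk_sim):
        panel, _, cfg, _ = desk_sim
        import dataclasses

        null = EffectsTable(3.0, np.zeros(panel.n_markers), panel.map.marker_id)
        reps = run_breeding_simulation(
            panel, null, panel.individual_ids[: cfg.n_parents],
            dataclasses.replace(cfg, cycles=4, replicates=1),
        )
        means = [m.mean_genetic_value for m in reps[0]]
        np.testing.assert_allclose(means, 3.0)

    def test_closed_population_allele_conservation(self, desk_sim):
        """No mutation/migration: any allele fixed in the founders stays fixed."""
        panel, eff, cfg, _ = desk_sim
        import dataclasses

        founders = panel.alleles[:8]
        fixed_one = founders.min(axis=(0, 1)) == 1
        fixed_zero = founders.max(axis=(0, 1)) == 0
        # run one replicate and inspect the final parents via heterozygosity 0/0
        reps = run_breeding_simulation(
            panel, eff, panel.individual_ids[:8],
            dataclasses.replace(cfg, cycles=5, replicates=1),
        )
        # conservation is structural (gametes only copy parental alleles);
        # verify the recorded heterozygosity at fixed loci cannot rise:
        # a fully fixed founder set must stay at het = 0 forever
        if fixed_one.all() or fixed_zero.all():
            assert all(m.expected_heterozygosity == 0 for m in reps[0])
        # direct check on gametes
        rng = np.random.default_rng(0)
        gmap = _GeneticMap(panel.map, 1.0)
        for _ in range(20):
            g = meiosis_gamete(founders[0], gmap, rng)
            assert set(np.unique(g)) <= set(np.unique(founders[0]))
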