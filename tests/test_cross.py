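import numpy as np
import pytest
from scipy import stats

from bsamap import (
    CrossDesign,
    QtlArchitecture,
    sample_pool_reads,
    select_extremes,
    simulate_cross,
)
from bsamap import engine
from bsamap.errors import ConfigError, SimulationError


class TestSelectExtremes:
    def test_published_pools_are_60_and_60(self, published_design, rng):
        pheno = rng.normal(size=600)
        large, small = select_extremes(pheno, published_design, rng)
        assert len(large) == len(small) == 60
        assert not set(large) & set(small)
        assert pheno[large].min() > pheno[small].max()

    def test_tied_phenotypes_split_randomly_but_disjointly(self, published_design, rng):
        pheno = np.zeros(600)
        large, small = select_extremes(pheno, published_design, rng)
        assert len(large) == len(small) == 60
        assert not set(large) & set(small)

    def test_tiny_cohort_takes_max_and_min(self, rng):
        design = CrossDesign(measured_females=10, pop_size=40)
        pheno = np.arange(10.0)
        large, small = select_extremes(pheno, design, rng)
        assert list(large) == [9] and list(small) == [0]

    def test_wrong_cohort_size_is_an_error(self, published_design, rng):
        with pytest.raises(SimulationError):
            select_extremes(np.zeros(10), published_design, rng)


class TestSamplePoolReads:
    def test_frequency_one_gives_only_large_parent_reads(self, rng):
        reads, totals = sample_pool_reads(np.ones(200), 50.0, rng)
        assert np.array_equal(reads, totals)

    def test_binomial_mean_at_half(self, rng):
        reads, totals = sample_pool_reads(np.full((2, 10_000), 0.5), 70.0, rng)
        frac = reads.sum() / totals.sum()
        assert abs(frac - 0.5) < 0.01

    def test_zero_depth_sites_are_emitted_with_zero_totals(self, rng):
        reads, totals = sample_pool_reads(np.full(100, 0.3), 0.0, rng)
        assert totals.sum() == 0 and reads.sum() == 0

    def test_invalid_inputs(self, rng):
        with pytest.raises(ConfigError):
            sample_pool_reads(np.array([0.5]), -1.0, rng)
        with pytest.raises(ConfigError):
            sample_pool_reads(np.array([1.5]), 10.0, rng)


class TestSimulateCross:
    def test_neutral_mean_ancestry_near_half(self, desk_design, desk_grid):
        rng = np.random.default_rng(11)
        means = []
        for _ in range(10):
            sim = simulate_cross(desk_design, grid=desk_grid, rng=rng)
            means.append(
                (sim.truth_freq_large.mean() + sim.truth_freq_small.mean()) / 2
            )
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_strong_single_locus_ranks_pools_deterministically(self, desk_grid):
        design = CrossDesign(
            f1_per_reciprocal_sex=25, pop_size=120, generations=8,
            measured_females=60, tail_fraction=0.10, env_sd=1e-9,
        )
        arch = QtlArchitecture.single("2L", 11_500_000, 100.0)
        rng = np.random.default_rng(12)
        for _ in range(5):
            sim = simulate_cross(design, arch, desk_grid, rng=rng)
            w = desk_grid.nearest_window("2L", 11_500_000)
            i = desk_grid.layout("2L").bit0 + w
            assert sim.truth_freq_large[i] > sim.truth_freq_small[i]

    def test_null_window_ad_is_symmetric_about_zero(self, desk_design, desk_grid):
        # two-sided sign test on per-replicate mean window ad, 200 replicates
        rng = np.random.default_rng(13)
        means = np.array(
            [
                np.nanmean(simulate_cross(desk_design, grid=desk_grid, rng=rng).ad)
                for _ in range(200)
            ]
        )
        assert abs(means.mean()) < 0.02
        n_pos = int((means > 0).sum())
        p = stats.binomtest(n_pos, len(means), 0.5).pvalue
        assert p > 0.01

    def test_qtl_outside_arm_is_config_error(self, desk_design, desk_grid):
        with pytest.raises(ConfigError):
            simulate_cross(
                desk_design, QtlArchitecture.single("2L", 99e9, 10.0), desk_grid, seed=1
            )

    def test_mosaic_blocks_tile_every_arm(self, desk_design, desk_grid):
        sim = simulate_cross(desk_design, grid=desk_grid, seed=14, keep_cohort=True)
        for mos in sim.mosaics()[:5]:
            for lay in desk_grid.layouts:
                for hom in mos.homologs[lay.arm.name]:
                    total = sum(e - s for s, e, _ in hom.blocks(lay.arm.length_bp))
                    assert total == pytest.approx(lay.arm.length_bp)


class TestPopulationGenetics:
    def test_drift_variance_follows_wright_fisher_recursion(self):
        # N=100, track one marker's population frequency across replicates
        from bsamap import Arm, WindowGrid

        grid = WindowGrid((Arm("2L", 10_000_000, 0.0),), {"2L": 3})
        design = CrossDesign(
            f1_per_reciprocal_sex=25, pop_size=100, generations=6,
            measured_females=50, tail_fraction=0.10,
        )
        rng = np.random.default_rng(15)
        freqs = []
        for _ in range(200):
            females = engine.run_population(design, grid, rng)
            bits = engine.unpack_cohort(females, grid)
            freqs.append(bits[:, :, 0].mean())
        # female-cohort frequency ~ population frequency at generation 6;
        # F1 (generation 1) starts at exactly 0.5
        t = design.generations - 1
        expected = 0.25 * (1 - (1 - 1 / (2 * design.pop_size)) ** t)
        var = np.var(freqs)
        assert 0.5 * expected < var < 2.0 * expected

    def test_junction_count_grows_with_generations(self, desk_grid):
        rng = np.random.default_rng(16)
        design = CrossDesign(
            f1_per_reciprocal_sex=25, pop_size=120, generations=2,
            measured_females=60, tail_fraction=0.10,
        )
        means = []
        gens = [2, 4, 6, 8, 10]
        for g in gens:
            d = CrossDesign(
                f1_per_reciprocal_sex=25, pop_size=120, generations=g,
                measured_females=60, tail_fraction=0.10,
            )
            females = engine.run_population(d, desk_grid, rng)
            bits = engine.unpack_cohort(females, desk_grid)
            lay = desk_grid.layout("2L")
            sl = slice(lay.bit0, lay.bit0 + lay.n_windows)
            switches = (np.diff(bits[:, :, sl].astype(int), axis=2) != 0).sum(axis=2)
            means.append(switches.mean())
        slope = stats.linregress(gens, means).slope
        assert slope > 0

    def test_sons_carry_a_single_x(self, full_grid):
        design = CrossDesign(
            f1_per_reciprocal_sex=25, pop_size=120, generations=4,
            measured_females=60, tail_fraction=0.10,
        )
        rng = np.random.default_rng(17)
        females, males = engine.founder_f1(full_grid, 50)
        for _ in range(3):
            females, males = engine._next_generation(rng, females, males, full_grid, 60, 60)
        x = full_grid.layout("X")
        assert (males[:, 0, x.byte0 : x.byte1] == males[:, 1, x.byte0 : x.byte1]).all()
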