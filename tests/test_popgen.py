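import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsamap import (
    Arm,
    HaplotypePanel,
    arm_quantile,
    chi_md,
    max_snp_fst,
    scan_panel,
    site_fst,
    window_fst,
)
from bsamap.errors import ConfigError


class TestSiteFst:
    def test_fixed_difference_is_one(self):
        assert site_fst(1.0, 0.0, 10, 10) == pytest.approx(1.0)

    def test_identical_frequencies_infinite_n_limit_is_zero(self):
        assert site_fst(0.5, 0.5, 10, 10, sample_correction=False) == pytest.approx(0.0)

    def test_worked_example_to_4dp(self):
        # (0.64 - 0.01 - 0.01) / 0.82
        assert site_fst(0.9, 0.1, 10, 10) == pytest.approx(0.7561, abs=5e-5)

    def test_small_samples_rejected(self):
        with pytest.raises(ConfigError):
            site_fst(0.5, 0.5, 1, 10)

    @given(
        st.tuples(
            st.floats(0, 1), st.floats(0, 1),
            st.integers(2, 500), st.integers(2, 500),
        )
    )
    def test_matches_direct_formula(self, tup):
        p1, p2, n1, n2 = tup
        ours = site_fst(p1, p2, n1, n2)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den == 0:
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(num / den, abs=1e-12)


class TestWindowFst:
    def test_single_site_window_equals_site_fst(self):
        assert window_fst(np.array([0.9]), np.array([0.1]), 10, 10) == pytest.approx(
            site_fst(0.9, 0.1, 10, 10)
        )

    def test_ratio_of_averages_arithmetic(self):
        # components (0.62, 0.82) and (0.0, 0.5) -> 0.62 / 1.32
        p1 = np.array([0.9, 0.5])
        p2 = np.array([0.1, 0.5])
        num1 = (0.8) ** 2 - 2 * 0.09 / 9
        num2 = -2 * 0.25 / 9
        den1, den2 = 0.82, 0.5
        expected = (num1 + num2) / (den1 + den2)
        assert window_fst(p1, p2, 10, 10) == pytest.approx(expected, abs=1e-12)

    def test_undifferentiated_window_is_nonpositive_corrected_zero_uncorrected(self):
        p = np.array([0.3, 0.5, 0.7])
        assert window_fst(p, p, 10, 10) <= 0
        assert window_fst(p, p, 10, 10, sample_correction=False) == pytest.approx(0.0)

    def test_no_usable_sites_is_missing(self):
        z = np.zeros(3)
        assert np.isnan(window_fst(z, z, 10, 10))


class TestMaxSnpFst:
    def test_fixed_difference_dominates(self):
        assert max_snp_fst(np.array([0.5, 1.0]), np.array([0.5, 0.0]), 50, 50) == pytest.approx(1.0)

    def test_monomorphic_shared_sites_are_missing(self):
        z = np.zeros(4)
        assert np.isnan(max_snp_fst(z, z, 10, 10))

    def test_takes_the_maximum(self):
        p1 = np.array([0.6, 0.9, 0.7])
        p2 = np.array([0.5, 0.1, 0.5])
        per_site = site_fst(p1, p2, 10, 10)
        assert max_snp_fst(p1, p2, 10, 10) == pytest.approx(np.nanmax(per_site))


def _panel_from(h1, h2, positions, length=100_000):
    arm = Arm("2L", length, 1.0)
    return HaplotypePanel(
        (arm,), {"2L": np.asarray(positions)},
        {"2L": np.asarray(h1, dtype=np.uint8)},
        {"2L": np.asarray(h2, dtype=np.uint8)},
    )


class TestChiMd:
    def test_identical_panels_score_zero(self):
        # two identical-pair-containing populations with the same structure
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, (3, 40), dtype=np.uint8)
        h = np.vstack([base, base[0]])  # haplotypes 0 and 3 identical
        pos = np.sort(rng.choice(100_000, 40, replace=False))
        panel = _panel_from(h, h.copy(), pos)
        vals = chi_md(panel, "2L", np.array([10]), np.array([20]))
        assert vals[0] == pytest.approx(0.0)

    def test_hand_computed_tract_contrast(self):
        # pop1: identical pair over the whole 100 kb arm -> tract 100 kb
        # pop2: identical only between discordant sites at 30 kb and 74 kb
        pos = np.array([10_000, 30_000, 45_000, 55_000, 74_000, 90_000])
        h1 = np.zeros((2, 6), dtype=np.uint8)
        h2 = np.zeros((2, 6), dtype=np.uint8)
        h2[1, 1] = 1   # discordant at 30 kb
        h2[1, 4] = 1   # discordant at 74 kb
        panel = _panel_from(h1, h2, pos)
        # window = sites 2..3 (45-55 kb), inside the 44 kb pop2 tract
        val = chi_md(panel, "2L", np.array([2]), np.array([3]))[0]
        assert val == pytest.approx((100_000 - 44_000) / 144_000, abs=5e-4)

    def test_discordance_inside_window_zeroes_the_tract(self):
        pos = np.array([10_000, 50_000, 90_000])
        h1 = np.zeros((2, 3), dtype=np.uint8)
        h2 = np.zeros((2, 3), dtype=np.uint8)
        h2[1, 1] = 1
        panel = _panel_from(h1, h2, pos)
        val = chi_md(panel, "2L", np.array([0]), np.array([2]))[0]
        assert val == pytest.approx(1.0)  # L2 = 0, L1 = arm length

    def test_window_outside_span_is_an_error(self):
        pos = np.array([10_000, 50_000])
        h = np.zeros((2, 2), dtype=np.uint8)
        panel = _panel_from(h, h, pos)
        with pytest.raises(ConfigError):
            chi_md(panel, "2L", np.array([1]), np.array([5]))


class TestArmQuantile:
    def test_strict_maximum_among_40(self):
        vals = np.concatenate(([100.0], np.arange(39)))
        q = arm_quantile(vals)
        assert q[0] == pytest.approx(1 / 40)

    def test_all_tied_share_quantile_one(self):
        assert arm_quantile(np.full(7, 3.3)).tolist() == [1.0] * 7

    def test_simple_ladder(self):
        assert arm_quantile(np.array([3.0, 2.0, 1.0])).tolist() == pytest.approx(
            [1 / 3, 2 / 3, 1.0]
        )

    def test_missing_values_excluded_from_both_counts(self):
        q = arm_quantile(np.array([3.0, np.nan, 1.0]))
        assert np.isnan(q[1]) and q[0] == pytest.approx(0.5) and q[2] == pytest.approx(1.0)


def test_scan_panel_quantile_of_arm_maximum(rng):
    from bsamap import GenomeConfig, gen_genome, gen_panels

    arms = (Arm("2L", 5_000_000, 10.0),)
    pos = gen_genome(GenomeConfig(arms=arms, snps_per_arm=600), seed=21)
    panel = gen_panels(pos, 12, 12, arms=arms, seed=21)
    scan = scan_panel(panel, snps_per_window=20)
    for stat in ("window_fst", "max_snp_fst", "chi_md"):
        col = scan[stat]
        top = scan.loc[col.idxmax()]
        ties = int((col == col.max()).sum())
        assert top["q_" + stat] == pytest.approx(ties / col.notna().sum())
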