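import numpy as np
import pandas as pd
import pytest

from bsamap import (
    CrossDesign,
    EffectCalibration,
    NullCalibration,
    calibrate_threshold,
    detect_qtls,
    estimate_effect_ci,
    estimate_power,
    null_detection_rate,
    summarize_crosses,
)
from bsamap.errors import ConfigError
from bsamap.qtl import local_maxima, max_flanking_excursion

from table1 import thorax_tables, wing_tables


def _null_calib(threshold=0.15):
    return NullCalibration(
        alpha=0.05,
        scope="arm",
        replicates=100,
        arm_names=["2L"],
        arm_maxima=np.full((100, 1), threshold / 2),
        threshold=threshold,
    )


def _effect_calib(design=None, sec_q95=0.08):
    rng = np.random.default_rng(0)
    effects = np.array([10.0, 20.0, 40.0])
    med = {10.0: 0.2, 20.0: 0.3, 40.0: 0.5}
    heights = {e: np.full(60, med[e]) + rng.normal(0, 1e-6, 60) for e in effects}
    offsets = {e: rng.normal(0, 500_000, 60) for e in effects}
    excursions = {e: np.linspace(0, sec_q95 / 0.95, 60) for e in effects}
    return EffectCalibration(
        design=design or CrossDesign(),
        effects=effects,
        sims_per_effect=60,
        heights=heights,
        offsets=offsets,
        excursions=excursions,
        null_heights=np.full(100, 0.075),
    )


def _profile(ad_by_win, arm="2L"):
    n = len(ad_by_win)
    return pd.DataFrame(
        {
            "arm": arm,
            "win": np.arange(n),
            "start": np.arange(n) * 10_000 + 1,
            "end": (np.arange(n) + 1) * 10_000,
            "mid": np.arange(n) * 10_000 + 5_000.0,
            "ad": ad_by_win,
        }
    )


class TestPeakGeometry:
    def test_local_maxima_of_a_ragged_profile(self):
        h = np.array([0.1, 0.3, 0.2, 0.25, 0.05, 0.4, 0.4, 0.1])
        assert local_maxima(h).tolist() == [1, 3, 5]

    def test_max_flanking_excursion(self):
        h = np.array([0.0, 0.3, 0.1, 0.25, 0.0])
        assert max_flanking_excursion(h, 1) == pytest.approx(0.15)
        assert max_flanking_excursion(np.array([0.3]), 0) == 0.0


class TestDetectQtls:
    def test_flat_profile_has_no_peaks(self):
        peaks = detect_qtls(_profile(np.zeros(50)), _null_calib())
        assert len(peaks) == 0

    def test_single_primary_peak(self):
        ad = np.zeros(50)
        ad[20:25] = [0.1, 0.2, 0.3, 0.2, 0.1]
        peaks = detect_qtls(_profile(ad), _null_calib(0.15), _effect_calib())
        assert len(peaks) == 1
        p = peaks.iloc[0]
        assert (p.cls, p.win) == ("primary", 22)
        assert p.effect == pytest.approx(20.0, abs=0.5)
        assert p.ci_lo <= p.pos <= p.ci_hi

    def test_negative_peak_reported_with_sign(self):
        ad = np.zeros(50)
        ad[10] = -0.4
        peaks = detect_qtls(_profile(ad), _null_calib(0.15), _effect_calib())
        assert peaks.iloc[0].ad == pytest.approx(-0.4)
        assert peaks.iloc[0].height == pytest.approx(0.4)

    def test_secondary_peak_needs_a_deep_enough_valley(self):
        ad = np.zeros(80)
        ad[20:25] = [0.1, 0.25, 0.35, 0.25, 0.1]     # primary
        ad[50:55] = [0.05, 0.15, 0.25, 0.15, 0.05]   # flanking bump
        calib = _null_calib(0.15)
        # excursion of the bump is 0.25 above a ~0 valley; threshold 0.08
        peaks = detect_qtls(_profile(ad), calib, _effect_calib(sec_q95=0.08))
        assert list(peaks.cls) == ["primary", "secondary"]
        assert peaks.iloc[1].win == 52
        # same profile, excursion threshold too high: bump not significant
        peaks2 = detect_qtls(_profile(ad), calib, _effect_calib(sec_q95=0.30))
        assert list(peaks2.cls) == ["primary"]

    def test_shoulder_of_a_single_peak_is_not_secondary(self):
        ad = np.zeros(80)
        ad[20:27] = [0.1, 0.25, 0.35, 0.30, 0.32, 0.2, 0.1]  # ragged shoulder
        peaks = detect_qtls(_profile(ad), _null_calib(0.15), _effect_calib(sec_q95=0.08))
        assert list(peaks.cls) == ["primary"]

    def test_missing_windows_are_bridged(self):
        ad = np.zeros(50)
        ad[20] = 0.4
        ad[15:19] = np.nan
        peaks = detect_qtls(_profile(ad), _null_calib(0.15), _effect_calib())
        assert peaks.iloc[0].win == 20


class TestEffectCalibration:
    def test_height_inversion_is_monotone_and_caps(self):
        ec = _effect_calib()
        e1, c1 = ec.effect_from_height(0.2)
        e2, c2 = ec.effect_from_height(0.3)
        e3, c3 = ec.effect_from_height(0.9)
        assert e1 == pytest.approx(10.0, abs=0.5)
        assert e2 == pytest.approx(20.0, abs=0.5)
        assert e1 < e2 < e3
        assert not c1 and not c2 and c3 and e3 == 40.0

    def test_offsets_translate_to_ci_around_peak(self):
        ec = _effect_calib()
        est = estimate_effect_ci(dict(ad=0.3, pos=5_000_000.0), ec, 20_000_000)
        assert est["ci_lo"] < 5_000_000 < est["ci_hi"]
        assert est["informative"]

    def test_null_level_height_is_flagged_non_informative(self):
        ec = _effect_calib()
        est = estimate_effect_ci(dict(ad=0.05, pos=5_000_000.0), ec, 20_000_000)
        assert not est["informative"]
        assert est["effect"] <= 10.0


class TestCalibrateThreshold:
    def test_refuses_noisy_quantiles(self, desk_design, desk_grid):
        with pytest.raises(ConfigError):
            calibrate_threshold(desk_design, desk_grid, replicates=50, seed=1)

    def test_alpha_zero_returns_the_sampled_maximum(self, desk_design, desk_grid):
        calib = calibrate_threshold(
            desk_design, desk_grid, replicates=20, alpha=0.0, seed=2, force=True
        )
        assert calib.threshold == pytest.approx(calib.max_ad_distribution.max())

    def test_alpha_monotonicity_on_the_same_sample(self, desk_design, desk_grid):
        calib = calibrate_threshold(
            desk_design, desk_grid, replicates=40, seed=3, force=True
        )
        pool = calib.max_ad_distribution
        assert np.quantile(pool, 0.99) >= np.quantile(pool, 0.95)

    def test_genome_scope_is_more_conservative(self, desk_design, desk_grid):
        rng = np.random.default_rng(4)
        arm = calibrate_threshold(desk_design, desk_grid, 60, scope="arm",
                                  rng=rng, force=True)
        genome = NullCalibration(
            alpha=0.05, scope="genome", replicates=60,
            arm_names=arm.arm_names, arm_maxima=arm.arm_maxima,
            threshold=float(np.quantile(arm.arm_maxima.max(axis=1), 0.95)),
        )
        assert genome.threshold >= arm.threshold


class TestPowerMachinery:
    def test_effect_out_of_range_rejected(self, desk_design, desk_grid):
        calib = _null_calib()
        with pytest.raises(ConfigError):
            estimate_power(desk_design, 0.0, calib, desk_grid, replicates=2)

    def test_null_detection_rate_matches_alpha(self, desk_design, desk_grid):
        calib = calibrate_threshold(desk_design, desk_grid, replicates=150, seed=5)
        rate = null_detection_rate(desk_design, calib, desk_grid,
                                   replicates=150, seed=6)
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_power_increases_with_effect(self, desk_design, desk_grid):
        calib = calibrate_threshold(desk_design, desk_grid, replicates=120, seed=7)
        p_lo = estimate_power(desk_design, 20.0, calib, desk_grid,
                              replicates=60, seed=8)
        p_hi = estimate_power(desk_design, 80.0, calib, desk_grid,
                              replicates=60, seed=8)
        assert p_hi >= p_lo


class TestSummarizeCrosses:
    def test_two_cross_overlap_rule(self):
        a = pd.DataFrame({"arm": ["2L"], "pos": [5e6], "ci_lo": [4e6],
                          "ci_hi": [6e6], "effect": [20.0]})
        b = pd.DataFrame({"arm": ["2L"], "pos": [5.5e6], "ci_lo": [5.2e6],
                          "ci_hi": [5.8e6], "effect": [10.0]})
        s = summarize_crosses({"a": a, "b": b})
        # b's peak is inside a's CI, but a's peak misses b's narrower CI
        assert s["overlapping_qtls"] == 1 and s["overlap_pct"] == 50
        assert s["avg_effect_pct"] == 15.0
        # widening b's CI to cover a's peak makes the overlap mutual
        b2 = b.assign(ci_lo=4.9e6)
        s2 = summarize_crosses({"a": a, "b": b2})
        assert s2["overlapping_qtls"] == 2 and s2["overlap_pct"] == 100

    def test_needs_at_least_two_crosses(self):
        with pytest.raises(ConfigError):
            summarize_crosses({"a": pd.DataFrame()})

    def test_published_thorax_summary(self):
        s = summarize_crosses(thorax_tables())
        assert s["total_qtls"] == 12
        assert s["avg_qtls_per_cross"] == 3.0
        assert s["overlap_pct"] == 0

    def test_published_wing_summary(self):
        s = summarize_crosses(wing_tables())
        assert s["total_qtls"] == 33
        assert s["avg_qtls_per_cross"] == 8.25
        assert s["overlapping_qtls"] == 12
        assert s["overlap_pct"] == 36
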