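"""Simulation-based QTL inference for bulk segregant profiles.

Significance, effect sizes and confidence intervals are all calibrated by
forward simulation of the actual cross design:

* a null calibration simulates the design with no QTLs and takes an upper
  quantile of the per-arm maximal |window ad| as the primary-peak
  significance threshold (pooled over arms; a genome-wide-maximum scope is
  available and is more conservative);
* an effect calibration simulates single QTLs over a grid of effect sizes,
  recording peak heights, peak-position offsets from the true position, and
  the size of flanking-peak excursions; observed peaks are then mapped to
  effects by inverting the monotone median height curve, and 90% CIs are
  read from the offset distribution at the estimated effect;
* secondary peaks are accepted when their excursion above the valley
  separating them from an established peak exceeds the 95th percentile of
  the same functional in single-QTL simulations (ragged single peaks do
  produce such excursions by chance, which is exactly what this test
  controls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross import CrossDesign, QtlArchitecture, simulate_cross
from .errors import ConfigError
from .genome import AUTOSOMES, WindowGrid


@dataclass
class NullCalibration:
    """Null distribution of peak heights and the derived threshold."""

    alpha: float
    scope: str                       # "arm" or "genome"
    replicates: int
    arm_names: list[str]
    arm_maxima: np.ndarray           # (replicates, n_arms)
    threshold: float

    @property
    def max_ad_distribution(self) -> np.ndarray:
        """The sampled maxima the threshold is a quantile of."""
        if self.scope == "genome":
            return self.arm_maxima.max(axis=1)
        return self.arm_maxima.ravel()


def calibrate_threshold(
    design: CrossDesign,
    grid: WindowGrid | None = None,
    replicates: int = 500,
    alpha: float = 0.05,
    scope: str = "arm",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snps_per_window: int = 50,
    force: bool = False,
) -> NullCalibration:
    """Simulate the design with no QTLs and return the (1 - alpha) quantile
    of maximal |window ad| as the primary-peak threshold.

    ``scope="arm"`` pools the per-arm maxima of every replicate (the null
    of the per-arm primary-peak test); ``scope="genome"`` uses the
    per-replicate genome-wide maximum (family-wise across arms).
    """
    if scope not in ("arm", "genome"):
        raise ConfigError(f"unknown scope {scope!r}")
    if replicates < 100 and not force:
        raise ConfigError(
            "fewer than 100 null replicates gives an unstable quantile; "
            "pass force=True to override"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    if grid is None:
        grid = WindowGrid.default()
    arm_names = grid.arm_names
    maxima = np.empty((replicates, len(arm_names)))
    null = QtlArchitecture.null()
    for r in range(replicates):
        sim = simulate_cross(design, null, grid, rng=rng, snps_per_window=snps_per_window)
        am = sim.arm_max()
        maxima[r] = [am[a] for a in arm_names]
    pool = maxima.ravel() if scope == "arm" else maxima.max(axis=1)
    threshold = float(np.quantile(pool, 1.0 - alpha))
    return NullCalibration(
        alpha=alpha,
        scope=scope,
        replicates=replicates,
        arm_names=arm_names,
        arm_maxima=maxima,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# peak geometry helpers


def _compress_nan(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop missing windows (bridging the span) and remember positions."""
    idx = np.nonzero(~np.isnan(values))[0]
    return values[idx], idx


def local_maxima(h: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a plateau counts once, at its left edge."""
    if len(h) == 0:
        return np.empty(0, dtype=int)
    keep = np.concatenate(([True], h[1:] != h[:-1]))
    ridx = np.nonzero(keep)[0]       # first index of each equal-value run
    hc = h[ridx]
    if len(hc) == 1:
        return ridx[:1]
    rise = np.concatenate(([True], hc[1:] > hc[:-1]))
    fall = np.concatenate((hc[:-1] > hc[1:], [True]))
    return ridx[rise & fall]


def max_flanking_excursion(h: np.ndarray, peak: int) -> float:
    """Largest (flanking local maximum - intervening valley) around ``peak``."""
    best = 0.0
    for m in local_maxima(h):
        if m == peak:
            continue
        lo, hi = (m, peak) if m < peak else (peak, m)
        valley = h[lo : hi + 1].min()
        best = max(best, float(h[m] - valley))
    return best


# ---------------------------------------------------------------------------
# effect calibration


@dataclass
class EffectCalibration:
    """Single-QTL response surface of the design.

    For each grid effect (percent of the parental difference), stores the
    simulated distribution of the QTL-arm peak height, of the offset
    (true - detected position, bp), and of the largest flanking excursion.
    """

    design: CrossDesign
    effects: np.ndarray                 # ascending, percent
    sims_per_effect: int
    heights: dict[float, np.ndarray]
    offsets: dict[float, np.ndarray]    # true_pos - detected_pos (bp)
    excursions: dict[float, np.ndarray]
    null_heights: np.ndarray | None = None

    def __post_init__(self) -> None:
        med = [float(np.median(self.heights[e])) for e in self.effects]
        self._grid_e = np.concatenate(([0.0], self.effects)) if self.null_heights is not None else np.asarray(self.effects, float)
        base = [float(np.median(self.null_heights))] if self.null_heights is not None else []
        # enforce monotonicity so height inversion is well defined
        self._grid_h = np.maximum.accumulate(np.asarray(base + med))

    @classmethod
    def build(
        cls,
        design: CrossDesign,
        grid: WindowGrid | None = None,
        effects=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 60.0, 100.0),
        sims_per_effect: int = 50,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        snps_per_window: int = 50,
        null_calib: NullCalibration | None = None,
    ) -> "EffectCalibration":
        if rng is None:
            rng = np.random.default_rng(seed)
        if grid is None:
            grid = WindowGrid.default()
        effects = np.sort(np.asarray(effects, dtype=float))
        if np.any(effects <= 0) or np.any(effects > 100):
            raise ConfigError("grid effects must lie in (0, 100]")
        arms = [a for a in grid.arm_names if a in AUTOSOMES] or grid.arm_names
        lengths = np.array([grid.layout(a).arm.length_bp for a in arms], float)
        heights, offsets, excursions = {}, {}, {}
        for e in effects:
            hs = np.empty(sims_per_effect)
            offs = np.empty(sims_per_effect)
            excs = np.empty(sims_per_effect)
            for i in range(sims_per_effect):
                arm = arms[rng.choice(len(arms), p=lengths / lengths.sum())]
                lay = grid.layout(arm)
                true_pos = rng.uniform(0, lay.arm.length_bp)
                sim = simulate_cross(
                    design,
                    QtlArchitecture.single(arm, true_pos, e),
                    grid,
                    rng=rng,
                    snps_per_window=snps_per_window,
                )
                h, idx = _compress_nan(np.abs(sim.arm_ad(arm)))
                peak = int(np.argmax(h))
                hs[i] = h[peak]
                offs[i] = true_pos - lay.mids[idx[peak]]
                excs[i] = max_flanking_excursion(h, peak)
            heights[float(e)] = hs
            offsets[float(e)] = offs
            excursions[float(e)] = excs
        return cls(
            design=design,
            effects=effects,
            sims_per_effect=sims_per_effect,
            heights=heights,
            offsets=offsets,
            excursions=excursions,
            null_heights=None if null_calib is None else null_calib.max_ad_distribution,
        )

    def median_height(self, effect: float) -> float:
        return float(np.interp(effect, self._grid_e, self._grid_h))

    def effect_from_height(self, height: float) -> tuple[float, bool]:
        """Invert the monotone median height curve; True flags capping at
        the largest calibrated effect."""
        if height >= self._grid_h[-1]:
            return float(self._grid_e[-1]), True
        return float(np.interp(height, self._grid_h, self._grid_e)), False

    def _nearest_effect(self, effect: float) -> float:
        return float(self.effects[np.argmin(np.abs(self.effects - effect))])

    def offset_interval(self, effect: float, level: float = 0.90) -> tuple[float, float]:
        """Central ``level`` interval of (true - detected) offsets, pooling
        the calibrated effects within 7.5 points of the estimate (at least
        the nearest grid effect) for quantile stability."""
        near = np.abs(self.effects - effect) <= 7.5
        if not near.any():
            near = self.effects == self._nearest_effect(effect)
        offs = np.concatenate([self.offsets[float(e)] for e in self.effects[near]])
        lo, hi = np.quantile(offs, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def secondary_threshold(self, effect: float, q: float = 0.95) -> float:
        """Excursion size exceeded by chance in only (1-q) of single-QTL
        simulations at the given effect."""
        e = np.asarray(self.effects)
        qs = np.array([np.quantile(self.excursions[float(x)], q) for x in e])
        return float(np.interp(effect, e, np.maximum.accumulate(qs)))


# ---------------------------------------------------------------------------
# peak calling


def _annotate_effect(row: dict, ec: EffectCalibration | None, lay) -> dict:
    if ec is None:
        row.update(effect=np.nan, ci_lo=np.nan, ci_hi=np.nan, capped=False)
        return row
    eff, capped = ec.effect_from_height(row["height"])
    lo_off, hi_off = ec.offset_interval(eff)
    ci_lo = max(1.0, row["pos"] + lo_off)
    ci_hi = min(float(lay.arm.length_bp), row["pos"] + hi_off)
    row.update(effect=eff, ci_lo=ci_lo, ci_hi=ci_hi, capped=capped)
    return row


def detect_qtls(
    profile: pd.DataFrame,
    calib: NullCalibration,
    effect_calib: EffectCalibration | None = None,
    max_peaks_per_arm: int = 10,
) -> pd.DataFrame:
    """Call significant primary and secondary QTL peaks from a windowed
    ancestry-difference profile.

    The per-arm maximum |ad| is the primary candidate and is significant if
    it reaches the calibrated threshold.  Flanking local maxima are then
    accepted greedily as secondary peaks while their excursion above the
    valley separating them from the nearest accepted peak exceeds the
    single-QTL excursion threshold at the primary's estimated effect.
    Missing windows are bridged.  Peaks are reported with the sign of their
    ad (a negative peak means small-parent alleles increase the trait).
    """
    out = []
    for arm, sub in profile.groupby("arm", sort=False):
        sub = sub.sort_values("win")
        h_all = sub["ad"].to_numpy()
        h, idx = _compress_nan(h_all)
        if len(h) == 0:
            continue
        habs = np.abs(h)
        mids = sub["mid"].to_numpy()[idx]
        wins = sub["win"].to_numpy()[idx]
        primary = int(np.argmax(habs))
        if habs[primary] < calib.threshold:
            continue
        accepted = [primary]
        rows = []
        row = dict(
            arm=arm, win=int(wins[primary]), pos=float(mids[primary]),
            ad=float(h[primary]), height=float(habs[primary]), cls="primary",
        )
        grid_lay = _ArmView(mids)
        rows.append(_annotate_effect(row, effect_calib, grid_lay))
        if effect_calib is not None:
            sec_thresh = effect_calib.secondary_threshold(rows[0]["effect"])
            cands = [m for m in local_maxima(habs) if m != primary]
            while cands and len(accepted) < max_peaks_per_arm:
                best, best_exc = None, -np.inf
                for m in cands:
                    nearest = min(accepted, key=lambda a: abs(a - m))
                    lo, hi = (m, nearest) if m < nearest else (nearest, m)
                    exc = habs[m] - habs[lo : hi + 1].min()
                    if exc > best_exc:
                        best, best_exc = m, exc
                if best_exc < sec_thresh:
                    break
                accepted.append(best)
                cands.remove(best)
                row = dict(
                    arm=arm, win=int(wins[best]), pos=float(mids[best]),
                    ad=float(h[best]), height=float(habs[best]), cls="secondary",
                )
                rows.append(_annotate_effect(row, effect_calib, grid_lay))
        out.extend(rows)
    cols = ["arm", "win", "pos", "ad", "height", "cls", "effect", "ci_lo", "ci_hi", "capped"]
    return pd.DataFrame(out, columns=cols)


class _ArmView:
    """Arm-extent stand-in derived from the profile itself (CI clamping)."""

    def __init__(self, mids: np.ndarray):
        class _A:
            length_bp = float(mids[-1]) if len(mids) else 0.0

        self.arm = _A()


def estimate_effect_ci(
    peak: pd.Series | dict,
    effect_calib: EffectCalibration,
    arm_length_bp: float | None = None,
) -> dict:
    """Fill effect size (% of the parental difference) and 90% CI (bp) for
    one significant peak via the calibrated response surface."""
    height = float(abs(peak["ad"]))
    eff, capped = effect_calib.effect_from_height(height)
    lo_off, hi_off = effect_calib.offset_interval(eff)
    ci_lo = peak["pos"] + lo_off
    ci_hi = peak["pos"] + hi_off
    ci_lo = max(1.0, ci_lo)
    if arm_length_bp is not None:
        ci_hi = min(float(arm_length_bp), ci_hi)
    informative = height > effect_calib.median_height(0.0) if effect_calib.null_heights is not None else True
    return dict(effect=eff, ci_lo=float(ci_lo), ci_hi=float(ci_hi),
                capped=capped, informative=bool(informative))


def estimate_power(
    design: CrossDesign,
    effect_pct: float,
    calib: NullCalibration,
    grid: WindowGrid | None = None,
    replicates: int = 200,
    criterion: str = "detect",
    effect_calib: EffectCalibration | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snps_per_window: int = 50,
) -> float:
    """Fraction of single-QTL replicates (random autosomal position) whose
    true arm carries a significant peak; with criterion="detect_and_cover"
    the peak's 90% CI must additionally cover the true position."""
    if not (0 < effect_pct <= 100):
        raise ConfigError("effect must be in (0, 100] percent")
    if criterion not in ("detect", "detect_and_cover"):
        raise ConfigError(f"unknown power criterion {criterion!r}")
    if criterion == "detect_and_cover" and effect_calib is None:
        raise ConfigError("detect_and_cover requires an EffectCalibration")
    if rng is None:
        rng = np.random.default_rng(seed)
    if grid is None:
        grid = WindowGrid.default()
    arms = [a for a in grid.arm_names if a in AUTOSOMES] or grid.arm_names
    lengths = np.array([grid.layout(a).arm.length_bp for a in arms], float)
    hits = 0
    for _ in range(replicates):
        arm = arms[rng.choice(len(arms), p=lengths / lengths.sum())]
        lay = grid.layout(arm)
        true_pos = rng.uniform(0, lay.arm.length_bp)
        sim = simulate_cross(
            design, QtlArchitecture.single(arm, true_pos, effect_pct),
            grid, rng=rng, snps_per_window=snps_per_window,
        )
        h, idx = _compress_nan(np.abs(sim.arm_ad(arm)))
        peak = int(np.argmax(h))
        if h[peak] < calib.threshold:
            continue
        if criterion == "detect":
            hits += 1
        else:
            pos = lay.mids[idx[peak]]
            est = estimate_effect_ci(
                dict(ad=h[peak], pos=pos), effect_calib, lay.arm.length_bp
            )
            if est["ci_lo"] <= true_pos <= est["ci_hi"]:
                hits += 1
    return hits / replicates


def null_detection_rate(
    design: CrossDesign,
    calib: NullCalibration,
    grid: WindowGrid | None = None,
    replicates: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snps_per_window: int = 50,
) -> float:
    """Per-arm false-positive rate of the threshold on fresh null data."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if grid is None:
        grid = WindowGrid.default()
    hits = 0
    total = 0
    for _ in range(replicates):
        sim = simulate_cross(design, QtlArchitecture.null(), grid, rng=rng,
                             snps_per_window=snps_per_window)
        for a in grid.arm_names:
            total += 1
            if np.nanmax(np.abs(sim.arm_ad(a))) >= calib.threshold:
                hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# cross summaries


def summarize_crosses(tables: dict[str, pd.DataFrame]) -> dict:
    """Combine per-cross QTL tables for one trait.

    A QTL "overlaps" when its peak midpoint lies inside another cross's 90%
    CI on the same arm.  Reports per-cross counts, the mean QTL count and
    mean effect size (2 decimals) and the overlap percentage (nearest
    integer), matching the precision of published summaries.
    """
    if len(tables) < 2:
        raise ConfigError("need QTL tables from at least 2 crosses")
    names = list(tables)
    total = sum(len(tables[n]) for n in names)
    overlapping = 0
    for name in names:
        df = tables[name]
        for _, q in df.iterrows():
            hit = False
            for other in names:
                if other == name:
                    continue
                o = tables[other]
                same = o[o["arm"] == q["arm"]]
                if ((same["ci_lo"] <= q["pos"]) & (q["pos"] <= same["ci_hi"])).any():
                    hit = True
                    break
            overlapping += hit
    effects = np.concatenate(
        [tables[n]["effect"].to_numpy(dtype=float) for n in names]
    ) if total else np.array([])
    return {
        "crosses": names,
        "qtls_per_cross": {n: int(len(tables[n])) for n in names},
        "total_qtls": int(total),
        "avg_qtls_per_cross": round(total / len(names), 2),
        "avg_effect_pct": round(float(np.nanmean(effects)), 2) if total else np.nan,
        "overlapping_qtls": int(overlapping),
        "overlap_pct": int(round(100.0 * overlapping / total)) if total else 0,
    }
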