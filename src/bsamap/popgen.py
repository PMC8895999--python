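"""Two-population differentiation and haplotype scans.

Three window statistics with complementary sensitivity to local adaptation:

* window F_ST (Hudson's estimator, ratio of averages) — strongest for hard
  sweeps whose linkage effects differentiate many SNPs at once;
* maximum SNP F_ST per window — strongest for narrow signals such as soft
  sweeps from standing variation, where few SNPs differentiate strongly;
* chi_MD, a haplotype-identity contrast — compares the physical lengths of
  identical haplotype tracts through the window between the two
  populations, large when the putatively adapted population carries long
  shared haplotypes (the footprint of a recent sweep).

Window values are ranked per chromosome arm by the "equal or greater"
quantile used for outlier calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome import Arm


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrices for two populations on shared sites.

    ``pop1`` is the putatively adapted population (Ethiopia in the
    motivating system), ``pop2`` the reference (Zambia); chi_MD is signed
    accordingly.
    """

    arms: tuple[Arm, ...]
    positions: dict[str, np.ndarray]
    pop1: dict[str, np.ndarray]   # (n1, n_sites) per arm
    pop2: dict[str, np.ndarray]
    labels: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        for arm in self.arms:
            a = arm.name
            if self.pop1[a].shape[1] != len(self.positions[a]) or self.pop2[
                a
            ].shape[1] != len(self.positions[a]):
                raise ConfigError(f"arm {a}: haplotype matrices do not match site list")
            for mat in (self.pop1[a], self.pop2[a]):
                if not np.isin(mat, (0, 1)).all():
                    raise ConfigError("haplotype matrices must be 0/1")

    @property
    def n1(self) -> int:
        return next(iter(self.pop1.values())).shape[0]

    @property
    def n2(self) -> int:
        return next(iter(self.pop2.values())).shape[0]


def site_fst(p1, p2, n1, n2, sample_correction: bool = True):
    """Hudson's per-site F_ST estimator.

    numerator   = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    May be negative; returns NaN where the denominator is zero.  With
    ``sample_correction=False`` the finite-sample terms are dropped (the
    infinite-n limit).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ConfigError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2
    if sample_correction:
        if n1 < 2 or n2 < 2:
            raise ConfigError("need at least 2 haplotypes per population")
        num = num - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def hudson_components(p1, p2, n1, n2, sample_correction: bool = True):
    """(numerator, denominator) arrays of Hudson's estimator per site."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    if sample_correction:
        num = num - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def window_fst(p1, p2, n1, n2, sample_correction: bool = True) -> float:
    """Ratio-of-averages Hudson F_ST over the sites of one window."""
    num, den = hudson_components(p1, p2, n1, n2, sample_correction)
    usable = den > 0
    if not usable.any():
        return np.nan
    return float(num[usable].sum() / den[usable].sum())


def max_snp_fst(p1, p2, n1, n2, sample_correction: bool = True) -> float:
    """Maximum per-site Hudson F_ST within one window."""
    vals = site_fst(p1, p2, n1, n2, sample_correction)
    vals = np.atleast_1d(vals)
    vals = vals[~np.isnan(vals)]
    return float(vals.max()) if len(vals) else np.nan


def _pair_tract_lengths(
    haps: np.ndarray,
    positions: np.ndarray,
    win_lo: np.ndarray,
    win_hi: np.ndarray,
    arm_length: float,
    pairs: np.ndarray,
) -> np.ndarray:
    """For each haplotype pair and window: physical length of the maximal
    interval containing the whole window over which the pair is identical
    at every panel site (0 if they disagree inside the window; bounded by
    the arm ends when no discordant site flanks the window)."""
    n_pairs = len(pairs)
    out = np.empty((n_pairs, len(win_lo)))
    for k, (i, j) in enumerate(pairs):
        disc = np.nonzero(haps[i] != haps[j])[0]
        if len(disc) == 0:
            out[k] = arm_length
            continue
        lo_rank = np.searchsorted(disc, win_lo)           # first discordant >= win_lo
        inside = (lo_rank < len(disc)) & (disc[np.minimum(lo_rank, len(disc) - 1)] <= win_hi)
        left = np.where(lo_rank > 0, positions[disc[np.maximum(lo_rank - 1, 0)]], 0.0)
        right = np.where(
            lo_rank < len(disc),
            positions[disc[np.minimum(lo_rank, len(disc) - 1)]],
            arm_length,
        )
        out[k] = np.where(inside, 0.0, right - left)
    return out


def chi_md(
    panel: HaplotypePanel,
    arm: str,
    win_lo: np.ndarray,
    win_hi: np.ndarray,
    max_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Haplotype-identity contrast per window.

    L1, L2 are the within-population mean pairwise identical-tract lengths
    through the window; returns (L1 - L2) / (L1 + L2) in (-1, 1), positive
    when the adapted population (pop1) carries longer shared haplotypes.
    Missing where both means are 0.  ``max_pairs`` caps the number of
    within-population pairs evaluated (seeded subsample) for large panels.
    """
    positions = panel.positions[arm]
    length = next(a.length_bp for a in panel.arms if a.name == arm)
    win_lo = np.asarray(win_lo)
    win_hi = np.asarray(win_hi)
    if np.any(win_lo < 0) or np.any(win_hi >= len(positions)) or np.any(win_lo > win_hi):
        raise ConfigError("window site span outside the covered sites")
    means = []
    for haps in (panel.pop1[arm], panel.pop2[arm]):
        n = haps.shape[0]
        if n < 2:
            raise ConfigError("need at least 2 haplotypes per population")
        pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
        if max_pairs is not None and len(pairs) > max_pairs:
            if rng is None:
                rng = np.random.default_rng(0)
            pairs = pairs[rng.choice(len(pairs), max_pairs, replace=False)]
        tr = _pair_tract_lengths(haps, positions, win_lo, win_hi, length, pairs)
        means.append(tr.mean(axis=0))
    l1, l2 = means
    tot = l1 + l2
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, (l1 - l2) / np.where(tot > 0, tot, 1.0), np.nan)


def arm_quantile(values: np.ndarray) -> np.ndarray:
    """Quantile of each window on its arm: the proportion of non-missing
    windows with an equal or greater value.  The strict arm maximum gets
    1/n; ties share the most inclusive rank (all equal -> all 1)."""
    values = np.asarray(values, dtype=float)
    out = np.full(len(values), np.nan)
    ok = ~np.isnan(values)
    v = values[ok]
    if len(v) == 0:
        return out
    order = np.argsort(v, kind="stable")
    # count of elements >= v_i = n - (number strictly less)
    strictly_less = np.searchsorted(v[order], v, side="left")
    out[ok] = (len(v) - strictly_less) / len(v)
    return out


def scan_panel(
    panel: HaplotypePanel,
    snps_per_window: int = 50,
    sample_correction: bool = True,
    max_pairs: int | None = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compute all three statistics in SNP-count windows plus per-arm
    quantiles.  Returns one row per window: arm, win, start, end,
    window_fst, max_snp_fst, chi_md and q_* quantile columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm in panel.arms:
        a = arm.name
        pos = panel.positions[a]
        h1, h2 = panel.pop1[a], panel.pop2[a]
        p1 = h1.mean(axis=0)
        p2 = h2.mean(axis=0)
        n1, n2 = h1.shape[0], h2.shape[0]
        n_sites = len(pos)
        lo = np.arange(0, n_sites, snps_per_window)
        hi = np.minimum(lo + snps_per_window - 1, n_sites - 1)
        wf = np.array([
            window_fst(p1[l : h + 1], p2[l : h + 1], n1, n2, sample_correction)
            for l, h in zip(lo, hi)
        ])
        mf = np.array([
            max_snp_fst(p1[l : h + 1], p2[l : h + 1], n1, n2, sample_correction)
            for l, h in zip(lo, hi)
        ])
        cm = chi_md(panel, a, lo, hi, max_pairs=max_pairs, rng=rng)
        df = pd.DataFrame(
            {
                "arm": a,
                "win": np.arange(len(lo)),
                "start": pos[lo],
                "end": pos[hi],
                "window_fst": wf,
                "max_snp_fst": mf,
                "chi_md": cm,
            }
        )
        for col in ("window_fst", "max_snp_fst", "chi_md"):
            df["q_" + col] = arm_quantile(df[col].to_numpy())
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
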