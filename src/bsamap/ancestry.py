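"""Per-SNP ancestry difference and SNP-count windowing.

The ancestry difference at a biallelic site is

    ad = (f_L - f_S) / (p_L - p_S)

where p_L is the frequency of the large parent's major allele in the large
parental strain, p_S that same allele's frequency in the small parental
strain, and f_L / f_S its read frequencies in the large and small offspring
pools.  Sites with |p_L - p_S| < 0.25 are excluded (noisy ancestry
estimates), retained SNPs are grouped into fixed-SNP-count windows, and the
window statistic is the unweighted mean ad over usable sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

#: minimum parental-strain allele frequency difference for a usable site
MIN_PARENT_DIFF = 0.25

BASES = ("A", "T", "C", "G")

SITE_COLUMNS = [
    "arm", "pos", "allele", "p_L", "p_S",
    "reads_L", "total_L", "reads_S", "total_S",
]


def site_table_from_sync(
    pool_sites,
    parent_sites,
    large_pool: int = 0,
    small_pool: int = 1,
    large_parent: int = 0,
    small_parent: int = 1,
) -> pd.DataFrame:
    """Join offspring-pool and parental sync records into a site table.

    For each position present in both files, the two most frequent bases
    across the parental pools define the biallelic site; the tracked allele
    is the large parent's major allele among those two.  N and deletion
    counts are ignored (biallelic SNP model).
    """
    parents = {(s.arm, s.pos): s for s in parent_sites}
    rows = []
    for s in pool_sites:
        par = parents.get((s.arm, s.pos))
        if par is None:
            continue
        cl = np.asarray(par.counts_per_pool[large_parent][:4], dtype=float)
        cs = np.asarray(par.counts_per_pool[small_parent][:4], dtype=float)
        tot = cl + cs
        if (tot > 0).sum() < 1:
            continue
        a1, a2 = np.argsort(tot)[::-1][:2]
        # major allele of the large parent among the two site alleles
        if cl[a1] + cl[a2] == 0:
            continue
        allele = a1 if cl[a1] >= cl[a2] else a2
        other = a2 if allele == a1 else a1
        denom_l = cl[allele] + cl[other]
        denom_s = cs[allele] + cs[other]
        if denom_l == 0 or denom_s == 0:
            continue
        p_L = cl[allele] / denom_l
        p_S = cs[allele] / denom_s
        ol = np.asarray(s.counts_per_pool[large_pool][:4], dtype=float)
        os_ = np.asarray(s.counts_per_pool[small_pool][:4], dtype=float)
        rows.append(
            (
                s.arm, s.pos, BASES[allele], p_L, p_S,
                ol[allele], ol[allele] + ol[other],
                os_[allele], os_[allele] + os_[other],
            )
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def filter_sites(sites: pd.DataFrame, min_parent_diff: float = MIN_PARENT_DIFF) -> pd.DataFrame:
    """Retain sites with |p_L - p_S| >= min_parent_diff (inclusive),
    preserving order."""
    keep = (sites["p_L"] - sites["p_S"]).abs() >= min_parent_diff
    return sites.loc[keep].reset_index(drop=True)


def site_ad(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site ancestry difference.

    Adds f_L, f_S (tracked-allele read fractions), ``ad`` and ``usable``
    (both pools covered).  ad may fall outside [-1, 1] through sampling
    noise; the sign is taken from the signed ratio, so a positive value
    always means the large pool is enriched for large-parent ancestry.
    """
    out = sites.copy()
    diff = out["p_L"] - out["p_S"]
    if np.any(diff == 0):
        raise ConfigError("site with p_L == p_S; filter sites before computing ad")
    usable = (out["total_L"] > 0) & (out["total_S"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_L = out["reads_L"] / out["total_L"]
        f_S = out["reads_S"] / out["total_S"]
        ad = (f_L - f_S) / diff
    out["f_L"] = f_L
    out["f_S"] = f_S
    out["ad"] = ad.where(usable)
    out["usable"] = usable
    return out


def build_windows(sites: pd.DataFrame, snps_per_window: int = 50) -> pd.DataFrame:
    """Group retained SNPs into consecutive fixed-count windows per arm.

    The final window of an arm may hold fewer SNPs; physical bounds are the
    first/last member SNP positions.  Arms with zero retained sites emit no
    windows (with a warning).
    """
    if snps_per_window < 1:
        raise ConfigError("snps_per_window must be >= 1")
    rows = []
    for arm, sub in sites.groupby("arm", sort=False):
        if len(sub) == 0:
            warnings.warn(f"arm {arm}: no retained sites, no windows built")
            continue
        pos = sub["pos"].to_numpy()
        loc = sub.index.to_numpy()
        for w, i0 in enumerate(range(0, len(sub), snps_per_window)):
            i1 = min(i0 + snps_per_window, len(sub))
            rows.append(
                (arm, w, int(pos[i0]), int(pos[i1 - 1]),
                 (pos[i0] + pos[i1 - 1]) / 2.0, i1 - i0, loc[i0], loc[i1 - 1])
            )
    return pd.DataFrame(
        rows, columns=["arm", "win", "start", "end", "mid", "n_sites", "i0", "i1"]
    )


def window_ad(windows: pd.DataFrame, site_ads: pd.DataFrame) -> pd.DataFrame:
    """Windowed profile: unweighted mean ad over usable sites per window;
    windows with no usable site get a missing value."""
    ad = site_ads["ad"].to_numpy(dtype=float)
    idx = site_ads.index.to_numpy()
    pos_of = {int(i): k for k, i in enumerate(idx)}
    out = windows.copy()
    means = np.empty(len(windows))
    for r, (i0, i1) in enumerate(zip(windows["i0"], windows["i1"])):
        vals = ad[pos_of[int(i0)] : pos_of[int(i1)] + 1]
        vals = vals[~np.isnan(vals)]
        means[r] = vals.mean() if len(vals) else np.nan
    out["ad"] = means
    return out.drop(columns=["i0", "i1"])


def ad_profile(
    sites: pd.DataFrame,
    snps_per_window: int = 50,
    min_parent_diff: float = MIN_PARENT_DIFF,
) -> pd.DataFrame:
    """Full scan: filter sites, compute per-site ad, window, average."""
    retained = filter_sites(sites, min_parent_diff)
    if len(retained) == 0:
        raise FormatError("no sites pass the parental-difference filter")
    ads = site_ad(retained)
    windows = build_windows(ads, snps_per_window)
    return window_ad(windows, ads)
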