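"""Outlier windows, merged outlier regions, and gene assignment.

Windows in the top 2.5% per-arm quantile for any of the three scan
statistics are outliers; neighbouring outlier windows separated by at most
2 non-outlier windows merge into one outlier region; each region collects
the genes overlapping its physical span plus, on any flank whose boundary
is not covered by a gene, the nearest gene in that direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError

STAT_COLUMNS = ("window_fst", "max_snp_fst", "chi_md")


def flag_outliers(scan: pd.DataFrame, cutoff: float = 0.025) -> pd.DataFrame:
    """Flag windows whose quantile is <= cutoff (inclusive) for any
    statistic; records which statistics triggered."""
    out = scan.copy()
    trig = []
    flags = np.zeros(len(scan), dtype=bool)
    for stat in STAT_COLUMNS:
        q = scan["q_" + stat].to_numpy()
        hit = ~np.isnan(q) & (q <= cutoff)
        flags |= hit
        trig.append(hit)
    out["outlier"] = flags
    out["stats"] = [
        ",".join(s for s, h in zip(STAT_COLUMNS, hits) if h)
        for hits in zip(*trig)
    ]
    return out


def merge_regions(flagged: pd.DataFrame, max_gap: int = 2) -> pd.DataFrame:
    """Merge outlier windows into regions, allowing up to ``max_gap``
    intervening non-outlier windows; regions never span arms.

    Physical spans run from the first to the last member *outlier* window.
    """
    if max_gap < 0:
        raise ConfigError("max_gap must be >= 0")
    regions = []
    for arm, sub in flagged.groupby("arm", sort=False):
        sub = sub.sort_values("win")
        wins = sub["win"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        stats = sub["stats"].to_numpy()
        out_idx = np.nonzero(sub["outlier"].to_numpy())[0]
        if len(out_idx) == 0:
            continue
        prev = out_idx[0]
        members = [out_idx[0]]
        for i in out_idx[1:]:
            if i - prev - 1 <= max_gap:
                members.append(i)
            else:
                regions.append(_region_row(arm, wins, starts, ends, stats, members))
                members = [i]
            prev = i
        regions.append(_region_row(arm, wins, starts, ends, stats, members))
    return pd.DataFrame(
        regions,
        columns=["arm", "win_first", "win_last", "start", "end",
                 "n_outlier_windows", "stats"],
    )


def _region_row(arm, wins, starts, ends, stats, members):
    trig = sorted({s for i in members for s in stats[i].split(",") if s})
    return (
        arm,
        int(wins[members[0]]),
        int(wins[members[-1]]),
        int(starts[members[0]]),
        int(ends[members[-1]]),
        len(members),
        ",".join(trig),
    )


def assign_genes(
    arm: str, start: int, end: int, genes: pd.DataFrame
) -> list[str]:
    """Genes associated with a region: all genes overlapping [start, end]
    (closed intervals), plus — for each flank whose boundary coordinate is
    not inside a gene — the nearest gene in that direction (edge-to-edge
    distance; ties toward the smaller start coordinate)."""
    sub = genes[genes["arm"] == arm]
    if len(sub) == 0:
        warnings.warn(f"arm {arm}: no genes annotated")
        return []
    gs = sub["start"].to_numpy()
    ge = sub["end"].to_numpy()
    ids = sub["gene_id"].to_numpy()
    overlap = (gs <= end) & (ge >= start)
    chosen = list(ids[overlap])
    left_covered = bool(np.any((gs <= start) & (ge >= start)))
    if not left_covered:
        cand = np.nonzero(ge < start)[0]
        if len(cand):
            d = start - ge[cand]
            best = cand[np.lexsort((gs[cand], d))][0]
            chosen.append(ids[best])
    right_covered = bool(np.any((gs <= end) & (ge >= end)))
    if not right_covered:
        cand = np.nonzero(gs > end)[0]
        if len(cand):
            d = gs[cand] - end
            best = cand[np.lexsort((gs[cand], d))][0]
            chosen.append(ids[best])
    seen: dict[str, None] = {}
    for g in chosen:
        seen.setdefault(g, None)
    return list(seen)


def assign_genes_to_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    out = regions.copy()
    out["genes"] = [
        ",".join(assign_genes(r.arm, r.start, r.end, genes))
        for r in regions.itertuples()
    ]
    return out


def qtl_intersect(regions: pd.DataFrame, qtls: pd.DataFrame) -> pd.DataFrame:
    """Annotate each region with the QTLs whose 90% CI overlaps it
    (closed-interval overlap on the same arm).  ``in_qtl`` marks the
    regions that feed the enrichment analysis."""
    out = regions.copy()
    hits = []
    for r in regions.itertuples():
        same = qtls[qtls["arm"] == r.arm]
        ov = same[(same["ci_lo"] <= r.end) & (same["ci_hi"] >= r.start)]
        hits.append(",".join(str(i) for i in ov.index))
    out["qtl_ids"] = hits
    out["in_qtl"] = [h != "" for h in hits]
    return out
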