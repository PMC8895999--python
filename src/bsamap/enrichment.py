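"""Permutation GO enrichment of outlier-region genes.

The observed statistic per GO term is the number of distinct outlier-region
genes annotated to it.  The null relocates every region to a uniformly
random window start on its own arm (preserving each region's window length
and keeping same-arm regions non-overlapping by rejection), re-assigns
genes and recounts.  P-values use the add-one convention
p = (#{permutation count >= observed} + 1) / (permutations + 1).
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from .errors import ConfigError
from .outliers import assign_genes


def observed_counts(gene_sets, go_map: dict[str, set[str]]) -> Counter:
    """Per-term counts over the union of region gene sets (a gene counts
    once per term however many regions it appears in)."""
    genes: set[str] = set()
    for gs in gene_sets:
        genes.update(gs)
    counts: Counter = Counter()
    for g in genes:
        for term in go_map.get(g, ()):
            counts[term] += 1
    return counts


def _arm_tables(windows: pd.DataFrame):
    tabs = {}
    for arm, sub in windows.groupby("arm", sort=False):
        sub = sub.sort_values("win")
        tabs[arm] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return tabs


def permutation_test(
    regions: pd.DataFrame,
    windows: pd.DataFrame,
    genes: pd.DataFrame,
    go_map: dict[str, set[str]],
    permutations: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 100,
) -> pd.DataFrame:
    """Permutation enrichment over all terms of ``go_map``.

    Returns one row per term: observed count, count of permutations with an
    equal or greater count, and the add-one p-value.
    """
    if permutations < 1:
        raise ConfigError("need at least 1 permutation")
    if rng is None:
        rng = np.random.default_rng(seed)
    arm_wins = _arm_tables(windows)
    reg = regions.reset_index(drop=True)
    lengths = (reg["win_last"] - reg["win_first"] + 1).to_numpy()
    arms = reg["arm"].to_numpy()
    for arm, ln in zip(arms, lengths):
        if arm not in arm_wins:
            raise ConfigError(f"region arm {arm!r} missing from the window table")
        if ln > len(arm_wins[arm][0]):
            raise ConfigError(f"region of {ln} windows longer than arm {arm!r}")

    gene_sets = [
        set(assign_genes(r.arm, r.start, r.end, genes)) for r in reg.itertuples()
    ]
    obs = observed_counts(gene_sets, go_map)
    terms = sorted({t for ts in go_map.values() for t in ts})
    obs_vec = np.array([obs.get(t, 0) for t in terms])

    ge_counts = np.zeros(len(terms), dtype=int)
    by_arm: dict[str, list[int]] = {}
    for i, arm in enumerate(arms):
        by_arm.setdefault(arm, []).append(i)

    warned = False
    for _ in range(permutations):
        perm_sets = [None] * len(reg)
        for arm, idxs in by_arm.items():
            w_start, w_end = arm_wins[arm]
            n_win = len(w_start)
            for attempt in range(max_attempts):
                placed = []
                ok = True
                for i in idxs:
                    ln = lengths[i]
                    s = int(rng.integers(0, n_win - ln + 1))
                    if any(s <= e2 and s + ln - 1 >= s2 for s2, e2 in placed):
                        ok = False
                        break
                    placed.append((s, s + ln - 1))
                if ok:
                    break
            else:
                if not warned:
                    warnings.warn(
                        f"arm {arm}: could not place regions without overlap "
                        f"after {max_attempts} attempts; allowing overlap"
                    )
                    warned = True
                placed = []
                for i in idxs:
                    s = int(rng.integers(0, n_win - lengths[i] + 1))
                    placed.append((s, s + lengths[i] - 1))
            for i, (s, e) in zip(idxs, placed):
                perm_sets[i] = set(
                    assign_genes(arm, int(w_start[s]), int(w_end[e]), genes)
                )
        counts = observed_counts(perm_sets, go_map)
        vec = np.array([counts.get(t, 0) for t in terms])
        ge_counts += vec >= obs_vec

    p = (ge_counts + 1) / (permutations + 1)
    out = pd.DataFrame(
        {
            "term": terms,
            "observed": obs_vec,
            "perm_greater_equal": ge_counts,
            "p": p,
        }
    )
    if len(out):
        # convenience column; the permutation p-values themselves are raw
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_bh"] = []
    return out
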