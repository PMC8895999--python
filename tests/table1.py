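"""Per-cross QTL tables reproducing the published mapping summaries.

The printed facts: four thorax crosses found 1, 2, 5 and 4 QTLs (total 12,
average 3) with no peak falling inside another cross's 90% CI; four wing
crosses found 12, 3, 10 and 8 QTLs (total 33, average 8.25) with 12 of the
33 QTLs overlapping (36%).  Positions/CIs are synthetic geometry built to
realize exactly those counts and overlap relations; effects are set to the
published per-trait averages.
"""

import itertools

import pandas as pd

ARMS = ("X", "2L", "2R", "3L", "3R")


def _isolated(n, start_slot, effect):
    """n QTLs with tight CIs, spaced so nothing overlaps anything."""
    rows = []
    for k in range(n):
        slot = start_slot + k
        arm = ARMS[slot % 5]
        pos = 1_000_000.0 * (2 + 2 * (slot // 5)) + 10_000 * (slot % 5)
        rows.append((arm, pos, pos - 50_000, pos + 50_000, effect))
    return rows


def thorax_tables() -> dict[str, pd.DataFrame]:
    counts = {"EF8N": 1, "EF15N": 2, "EF73N": 5, "EF86N": 4}
    tables = {}
    slot = 0
    for name, n in counts.items():
        rows = _isolated(n, slot, 15.0)
        slot += n
        tables[name] = pd.DataFrame(
            rows, columns=["arm", "pos", "ci_lo", "ci_hi", "effect"]
        )
    return tables


def wing_tables() -> dict[str, pd.DataFrame]:
    counts = {"EF8N": 12, "EF15N": 3, "EF73N": 10, "EF86N": 8}
    # six mutually-overlapping pairs involving 12 distinct QTLs:
    # member counts per cross 4 / 1 / 4 / 3
    pairs = [
        ("EF8N", "EF15N"), ("EF8N", "EF73N"), ("EF8N", "EF86N"),
        ("EF73N", "EF86N"), ("EF8N", "EF73N"), ("EF73N", "EF86N"),
    ]
    rows = {name: [] for name in counts}
    base = 5_000_000.0
    for k, (a, b) in enumerate(pairs):
        center = base + 3_000_000.0 * k
        rows[a].append(("3R", center, center - 800_000, center + 800_000, 17.0))
        rows[b].append(("3R", center + 400_000, center - 400_000, center + 1_200_000, 17.0))
    slot = 100  # isolated QTLs live in a distant coordinate block
    for name, n in counts.items():
        missing = n - len(rows[name])
        rows[name].extend(_isolated(missing, slot, 17.0))
        slot += missing
    return {
        name: pd.DataFrame(r, columns=["arm", "pos", "ci_lo", "ci_hi", "effect"])
        for name, r in rows.items()
    }
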