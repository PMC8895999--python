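"""Round-trip a simulated cross through PoPoolation2 sync files.

Writes the pooled-sequencing output of a simulated cross as sync files
(large pool, small pool, and the two parents as pools), reads them back,
rebuilds the site table, applies the >=0.25 parental-difference filter and
recomputes the windowed ancestry difference from raw counts — the same path
a real experiment's data takes through the package.
"""

import pathlib
import tempfile

import numpy as np

from bsamap import (
    CrossDesign,
    GenomeConfig,
    QtlArchitecture,
    WindowGrid,
    ad_profile,
    filter_sites,
    gen_genome,
    gen_parental_pair,
    simulate_cross,
    site_table_from_sync,
    sync_from_sim,
)
from bsamap.formats import read_sync, write_sync

design = CrossDesign()
grid = WindowGrid.default()
sim = simulate_cross(design, QtlArchitecture.single("2R", 12_000_000, 30.0),
                     grid, seed=23)

positions = gen_genome(GenomeConfig(snps_per_arm=2000), seed=24)
sites = gen_parental_pair(positions, fixed_diff_fraction=0.7,
                          residual_het=0.1, seed=25)
pools, parents = sync_from_sim(sim, sites, seed=26)

tmp = pathlib.Path(tempfile.mkdtemp())
write_sync(pools, tmp / "pools.sync")
write_sync(parents, tmp / "parents.sync")
print(f"wrote {len(pools)} sites to {tmp}/pools.sync (+ parents.sync)")

table = site_table_from_sync(read_sync(tmp / "pools.sync", 2),
                             read_sync(tmp / "parents.sync", 2))
retained = filter_sites(table)
print(f"{len(table)} sites re-read; {len(retained)} pass the >=0.25 "
      f"parental-difference filter "
      f"({len(table) - len(retained)} low-difference sites dropped)")

profile = ad_profile(table, snps_per_window=50)
arm = profile[profile.arm == "2R"]
peak = arm.iloc[int(arm.ad.abs().idxmax() - arm.index[0])]
print(f"\nrecomputed profile: {len(profile)} windows; "
      f"2R peak ad = {peak.ad:+.3f} at {peak.mid/1e6:.2f} Mb "
      f"(true QTL at 12.0 Mb, 30% effect)")
print("The sync round trip reproduces the in-memory scan's signal.")
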