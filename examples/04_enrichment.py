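"""Permutation GO enrichment of outlier-region genes.

Builds a synthetic annotation, plants outlier regions on top of the genes
of one GO term, and shows that the permutation test (regions relocated
uniformly on their arm, lengths preserved) flags that term while unrelated
terms stay near p = 1.
"""

import numpy as np
import pandas as pd

from bsamap import Arm, assign_genes, gen_annotation, permutation_test

arm = Arm("2L", 20_000_000, 44.0)
genes, go = gen_annotation((arm,), genes_per_arm=200, terms=15,
                           mean_genes_per_term=12, seed=9)

# window grid for the permutation null (400 x 50 kb windows)
n_win = 400
windows = pd.DataFrame({
    "arm": "2L",
    "win": np.arange(n_win),
    "start": np.arange(n_win) * 50_000 + 1,
    "end": (np.arange(n_win) + 1) * 50_000,
})

# place regions over the first three genes of GO:0000001
target = sorted(g for g, ts in go.items() if "GO:0000001" in ts)[:3]
rows = []
for g in target:
    span = genes[genes.gene_id == g].iloc[0]
    w0 = int((span.start - 1) // 50_000)
    rows.append(("2L", w0, w0, int(windows.start[w0]), int(windows.end[w0])))
regions = pd.DataFrame(rows, columns=["arm", "win_first", "win_last", "start", "end"])

res = permutation_test(regions, windows, genes, go, permutations=2000, seed=9)
res = res.sort_values("p").reset_index(drop=True)

print("regions placed on 3 genes of GO:0000001; 2000 permutations\n")
print(res.head(5).to_string(index=False))
print("\nGO:0000001 gets a small permutation p-value (it can never reach 0:")
print("the add-one convention bounds it at 1/(permutations+1)); terms whose")
print("genes the regions merely flank by chance stay unremarkable.")
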