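# bsamap

Bulk segregant QTL mapping and local-adaptation scans for crosses between
divergent populations, built around the design used to map body- and
wing-size evolution in highland *Drosophila melanogaster*: two inbred
strains (a large highland "E" parent and a small lowland "Z" parent) are
crossed, the offspring interbreed for ~16 generations at large census size,
and the phenotypic extremes of the final generation are pool-sequenced.

It is a library first — `import bsamap` — with short narrative scripts in
`examples/` and a thin `bsamap` command-line wrapper.  It is aimed at
people designing or analyzing pool-seq BSA experiments who need calibrated
significance, effect sizes, and power for *their* design rather than
rule-of-thumb thresholds.

## What it computes

**Ancestry difference.**  For each biallelic SNP with parental allele
frequencies `p_L` (large parent's major allele) and `p_S`, and pool read
frequencies `f_L`, `f_S` of that allele,

```
ad = (f_L − f_S) / (p_L − p_S)
```

Sites with |p_L − p_S| < 0.25 are dropped, retained SNPs are windowed by
count, and windows average `ad`.  A QTL where E alleles increase the trait
pulls `ad` up; noise comes mostly from which 60 flies land in each pool.

**Simulation-calibrated inference.**  The same forward simulator that
generates data calibrates it: significance thresholds are null quantiles of
the maximal window `ad`, effect sizes invert a simulated effect→peak-height
response, 90% CIs come from simulated peak-position offsets, and power
curves are replicate detection fractions (`bsamap.qtl`).

**Local-adaptation scans.**  Window F_ST (Hudson), maximum SNP F_ST per
window, and a haplotype-identity contrast (chi_MD) over two phased panels,
ranked by per-arm quantiles; top-2.5% windows merge into outlier regions
(≤ 2 intervening non-outliers), regions collect overlapping plus nearest
flanking genes, intersect QTL CIs, and feed a permutation GO enrichment
(regions relocated on their arm, 10,000 permutations, add-one p-values)
(`bsamap.popgen`, `bsamap.outliers`, `bsamap.enrichment`).

**Synthetic data.**  Generators for SNP maps, parental site tables,
two-population haplotype panels with plantable hard/soft sweeps, gene/GO
annotations, and sync-file output of simulated crosses (`bsamap.synthetic`),
so the whole pipeline runs without any external data.

## Worked example

`examples/01_simulate_cross.py` simulates the published design (N = 1,200,
16 generations, 600 measured females, 10% tails of 60 flies, 70× merged
pools) with two planted QTLs:

```
per-arm maximum |ad| (the peak candidates):
   X: 0.193
  2L: 0.316
  2R: 0.227
  3L: 0.170
  3R: 0.157

QTL 2L:8.0 Mb (effect 25%):
  window ad from reads     = 0.304
  true pool ancestry diff  = 0.292

QTL 3R:20.0 Mb (effect 15%):
  window ad from reads     = 0.111
  true pool ancestry diff  = 0.108

background (X arm, no QTL): mean ad +0.013, sd 0.058
```

The 25% QTL towers over the pool-sampling noise (±0.06 per window); the
15% QTL is at the detection edge — which is why significance must be
calibrated against the design's own null rather than eyeballed.
`examples/02_qtl_calling.py` does that calibration and prints called peaks
with effects and CIs; `03`–`05` walk the popgen scan, the enrichment test,
and the sync-file round trip.

## Command line

```
bsamap simulate   --config cfg.yaml --seed 1 --out run/
bsamap ad-scan    --sync pools.sync --parents parents.sync --out profile.tsv
bsamap qtl-call   --profile profile.tsv --null-reps 500 --seed 1 --out qtls.tsv
bsamap popgen-scan --panel panel.tsv --out scan.tsv
bsamap outliers   --scan scan.tsv --genes genes.bed --qtls qtls.tsv --out regions.tsv
bsamap enrich     --regions regions.tsv --windows scan.tsv --genes genes.bed \
                  --go go.tsv --perms 10000 --seed 1 --out enrichment.tsv
bsamap summarize  cross1.tsv cross2.tsv cross3.tsv cross4.tsv
```

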