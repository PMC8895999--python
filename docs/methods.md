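# Methods

`bsamap` implements quantitative-trait-locus (QTL) mapping by bulk segregant
analysis (BSA) of a cross between two divergent *Drosophila melanogaster*
populations — a large-bodied highland (Ethiopia-like, "E") strain and a
small-bodied lowland (Zambia-like, "Z") strain — together with the
population-genetic outlier machinery used to nominate candidate genes inside
mapped QTLs.  This note records the models, their assumptions, the defaults,
and the design choices made where the procedure was genuinely open.

## The cross model

The experimental design being modeled: reciprocal crosses between one inbred
E and one inbred Z strain; 125 F1 offspring per sex per reciprocal direction
found the population; non-overlapping generations of random mating at a
census size of ~1,200 with no selection; at generation 16, 600 adult females
are measured for the trait and the 10% largest (60) and 10% smallest (60)
are pooled for sequencing, each tail as two 30-fly subpools (0–5% and 5–10%
extremes) whose reads are merged.

**Genome representation.** Parents are fully inbred, so every chromosome is
a mosaic of E and Z blocks.  The reference representation
(`bsamap.mosaic`) stores exact breakpoint lists.  The population engine
(`bsamap.engine`) instead tracks ancestry at one marker per analysis window
(14,107 markers over arms X/2L/2R/3L/3R by default), bit-packed per arm.
Because crossovers between adjacent markers compose by parity, the marker
process is the exact projection of the continuous process onto window
midpoints; nothing is approximated at the window scale the analysis uses.

**Meiosis.** Female meiosis draws per-arm crossover counts
Poisson(cM/100) with uniform placement on the genetic map (linear bp↔cM by
default) and no interference.  Males are achiasmate — standard for
*D. melanogaster* — and transmit one intact homolog per arm (configurable
off via `CrossDesign(male_recomb=True)` for generic organisms).  Arms
assort independently; centromeric linkage between e.g. 2L and 2R is not
modeled.  The X is transmitted with standard sex linkage (sons receive the
maternal X only); sex ratio is exactly 1:1 each generation and parents are
drawn uniformly with replacement (Wright–Fisher).

**Phenotype and selection.** The trait is additive across QTLs: each E
allele at a locus of effect *e* (given as a percentage of the parental
strain difference) adds *e*/2 trait units, so an all-E homozygote exceeds
an all-Z homozygote by the summed effects.  Environmental noise is Gaussian
with `env_sd = 1/3` by default, i.e. the parental difference spans 3
environmental standard deviations (an h²-style knob; no empirical value is
available for the motivating traits).  Tails are selected by truncation of
the 600 measured females with seeded random tie-breaking.

**Sequencing.** Per site, each subpool contributes Poisson(depth/2) reads
(70× merged per pool by default — typical for this design; actual depths
are experiment-specific) and E-allele reads are Binomial(total, subpool
frequency).  For window-level work the engine aggregates the
`snps_per_window` (default 50) fixed-difference SNPs of a window into one
Poisson/binomial draw at the summed depth; at these depths this is
distributionally indistinguishable from per-site sampling followed by the
within-window mean (the two estimators differ only through the
E[1/depth] vs 1/E[depth] correction, <2% of the window variance).

## The ancestry-difference scan

For each biallelic SNP,

    ad = (f_L − f_S) / (p_L − p_S)

where `p_L` is the frequency of the large parent's major allele in the
large parental strain, `p_S` that allele's frequency in the small parental
strain, and `f_L`, `f_S` its read frequencies in the large and small
offspring pools.  Sites with |p_L − p_S| < 0.25 are removed before
windowing (noisy ancestry estimates); the threshold is inclusive.  Retained
SNPs are grouped into fixed-count windows (SNP-density windowing; the final
window of an arm may be short) and the window statistic is the unweighted
mean over usable sites (sites with reads in both pools).  `ad` can exceed
[−1, 1] by sampling noise; its sign is meaningful (negative peaks mean
small-parent alleles increase the trait) and no re-polarization is applied
— the ratio is self-normalizing even when p_L < p_S.

## Simulation-calibrated inference

**Threshold.** `calibrate_threshold` simulates the full design with no
QTLs and takes the 95th percentile (α = 0.05) of maximal |window ad|.  Two
scopes are exposed: the default `"arm"` pools the per-arm maxima across
replicates — the null of the per-arm primary-peak test that `detect_qtls`
performs — and `"genome"` uses per-replicate genome-wide maxima
(family-wise across arms, more conservative).  Under the default design the
arm-scope threshold is ≈ 0.22–0.23 and the genome scope ≈ 0.25.

The threshold is dominated by pool-composition noise, which has a
design-intrinsic floor: with two disjoint pools of n flies drawn from N
measured, Var(f_L − f_S) ≈ 2·p(1−p)/(2n) · (1 − n/N), about 0.06 SD per
window at n = 60, N = 600 — read depth and window SNP counts contribute
little beyond it.  The calibrated threshold therefore scales as 1/√n in
the pool size and is insensitive to most other knobs; analyses of this
design that assume larger pools or smoother profiles will quote
correspondingly lower thresholds.

**Peak calling.** Per arm the maximal |window ad| is the primary
candidate, significant if it reaches the threshold.  Secondary peaks:
ragged single-QTL profiles show flanking local maxima by chance, so a
flanking maximum is accepted only when its excursion above the valley
separating it from the nearest accepted peak exceeds the 95th percentile of
the same functional in single-QTL simulations at the primary's estimated
effect; accepted peaks are added greedily until no candidate passes.
Missing windows are bridged.  This operationalization of the
"is the ragged peak really two QTLs?" question is this package's own; other
simulation-based BSA tools implement the idea differently.

**Effects and confidence intervals.** `EffectCalibration` simulates single
QTLs at uniformly random autosomal positions over an effect grid (default
5–100%, 50 replicates each), recording (i) the QTL-arm peak height, (ii)
the offset between true and detected peak position, and (iii) the flanking
excursion sizes.  The median height curve is monotonized
(`np.maximum.accumulate`) and inverted by linear interpolation to map an
observed peak height to an effect estimate — equivalent to bisection
against the same monotone response, but the simulations are reused across
peaks, which is what makes calibrated effect estimation affordable.
Heights above the largest calibrated effect are capped and flagged; heights
at or below the null median are flagged non-informative.  The 90% CI is the
central 90% interval of (true − detected) offsets at the estimated effect
(pooling grid effects within 7.5 points for quantile stability), translated
to the observed peak and clamped to the arm.

**Power.** `estimate_power` is the fraction of single-QTL replicates whose
true arm carries a significant peak ("detect"); a stricter variant
additionally requires the 90% CI to cover the true position
("detect_and_cover").  At the default design the detection power for a 20%
effect is ≈ 0.87–0.92 at the arm-calibrated threshold and > 0.99 at a 0.17
threshold; at effect 0 the per-arm detection rate equals α by construction.

**Cross summaries.** `summarize_crosses` counts QTLs per cross, averages
effects, and computes the pairwise overlap percentage, where a QTL
"overlaps" if its peak midpoint lies inside another cross's 90% CI on the
same arm.  Averages are reported to 2 decimals and percentages to the
nearest integer, the precision used in published summaries of this design.

## Population-genetic scans

All three statistics are computed in SNP-count windows and ranked per arm
by the inclusive quantile q(w) = #{windows with value ≥ value(w)} / #windows
(missing windows excluded from both counts).

* **Window F_ST** — Hudson's estimator with finite-sample correction,
  numerator (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1), denominator
  p1(1−p2) + p2(1−p1), combined as a ratio of sums over the window.
  Negative values are kept (clamping would distort the outlier tail).
* **SNP F_ST** — the maximal per-site Hudson value in the window.
* **chi_MD** — a haplotype-identity contrast: for every within-population
  haplotype pair, the physical length of the maximal interval containing
  the whole window over which the pair is identical at all panel sites
  (0 if they disagree inside the window; extended to the arm bounds when no
  discordant site flanks it); with L1, L2 the within-population means, the
  statistic is (L1 − L2)/(L1 + L2), positive when the putatively adapted
  population carries longer shared haplotypes.  The exact functional is
  this package's operationalization of the verbal definition of the
  haplotype-contrast family of statistics.  Caveat: the normalized contrast
  saturates at ±1 whenever one population shows no identity at all through
  a window (mean tract 0), regardless of the other population's tract
  lengths; windows should therefore hold few enough SNPs that
  within-population identity is common (≈10 SNPs per window works well for
  panels of a few dozen haplotypes), otherwise saturated background windows
  crowd the outlier tail.  For large panels the pair set can be subsampled
  (`max_pairs`, seeded).

Hard sweeps elevate window F_ST and chi_MD over a broad span; soft sweeps
(two sweeping cores) concentrate the signal in single SNPs and elevate SNP
F_ST — the sensitivity contrast that motivates using all three.

## Outlier regions, genes, enrichment

Windows in the top 2.5% per-arm quantile (inclusive) for **any** statistic
are outliers; outliers separated by ≤ 2 non-outlier windows merge into
regions (never across arms; spans run from first to last member outlier
window).  A region collects all genes overlapping its span plus, on each
flank whose boundary coordinate is not inside a gene, the nearest gene in
that direction (edge-to-edge distance, ties toward the smaller start).
Regions are linked to QTLs by closed-interval overlap with the 90% CI;
regions outside every QTL are kept in reports but excluded from enrichment.

Enrichment: the observed statistic per GO term is the number of distinct
region genes annotated to it.  Permutations relocate every region to a
uniformly random window start on its own arm — preserving its window length
and keeping same-arm regions disjoint by rejection — then re-assign genes
and recount; p = (#{count ≥ observed} + 1)/(permutations + 1) (add-one, so
p is never 0; default 10,000 permutations).  Relocation preserving length
and arm conserves each region's gene-count opportunity, which is the
closest null to "regions were randomly reassigned".  P-values are raw; a
Benjamini–Hochberg column is emitted as a convenience only.  Because counts
are discrete, null p-values are super-uniform (conservative), markedly so
when expected per-term counts are small.

## Synthetic data

The generators produce everything the pipeline reads: SNP positions
(uniform, distinct, per arm), parental site tables with exact-count
mixtures of fixed differences, residual-heterozygosity sites (one parent at
0.5 — inbred lines retain some heterozygosity) and sub-threshold sites that
exercise the 0.25 filter; two-population haplotype panels (ancestral
frequencies Beta(0.2, 0.2), population frequencies by Balding–Nichols drift
at a configurable background F_ST, default 0.05); localized hard/soft
sweeps in which the swept allele is forced to be the minor allele of the
unswept population at the center site (a locally adaptive variant rare in
the source population); tiled non-overlapping gene annotations and
Poisson-sized GO terms; and sync files rendered from simulated crosses.

What the synthetic data does **not** emulate: coalescent linkage
disequilibrium and realistic site-frequency correlations along the
chromosome (background sites are independent given the drift model),
inversion polymorphism, SNP ascertainment, mutation/gene conversion,
variable recombination maps, or segregating founder heterozygosity inside
the cross simulator (residual heterozygosity appears only in parental site
frequencies — Eq-normalization by the parental difference absorbs it).
Passing tests therefore demonstrate the statistical machinery under a
clean, known-truth model, not robustness to every feature of real data.

## Numerical choices and degenerate inputs

Seeded `numpy.random.Generator` throughout; every stochastic entry point
takes `seed=`/`rng=`.  Phenotype ties are broken by seeded jitter.  Windows
with no usable site propagate as missing and are bridged in peak geometry.
Zero-depth sites are emitted with zero totals and excluded from window
means.  A 0 cM arm never recombines.  Monotone curves are enforced by
running maxima before inversion.  Quantile thresholds use the empirical
(linear-interpolation) quantile; α = 0 returns the sampled maximum.
Calibration refuses < 100 replicates unless forced.

## Problem sizes of the default verification runs

The bundled test-suite checks run the full published design at 250 null
replicates (threshold), 200 power replicates, 200 recovery replicates with
a 7-point effect grid × 60 simulations, 200 enrichment-null runs × 99
permutations, and 10 seeds per sweep mode; `scripts/acceptance.py` uses 500
null and 200 power replicates.  These sizes keep the whole verification in
the tens of minutes on one core while leaving Monte-Carlo error well inside
the tolerances asserted.

## Known limitations

* The significance threshold is specific to the calibrated null; its
  absolute value is dominated by pool size (1/√n) and differs from values
  quoted for this design by tools whose null models smooth profiles or
  assume larger pools.
* Effect estimates for secondary peaks reuse the single-QTL response
  surface; overlapping QTLs bias them upward.
* Additive effects only — no dominance, epistasis, or X-dosage phenotypic
  modeling; arms assort independently in meiosis.
* chi_MD saturation (above) makes its outlier tail window-size dependent.
* The enrichment null relocates regions independently per permutation
  attempt; with very dense regions on short arms, non-overlap placement can
  fail and falls back to allowing overlap with a warning.
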