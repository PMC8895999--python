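"""Bulk-segregant cross simulation.

Models the mapping experiment end to end: reciprocal F1s between an inbred
large (Ethiopia) and small (Zambia) strain, random-mating interbreeding at
constant census size with no selection, phenotyping of final-generation
females under an additive QTL model plus Gaussian environmental noise,
truncation selection of the phenotypic tails into two sequencing pools, and
Poisson/binomial read sampling of pooled DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .errors import ConfigError, SimulationError
from .genome import WindowGrid


@dataclass(frozen=True)
class CrossDesign:
    """Parameters of the mapping cross.

    Defaults mirror the experiment: reciprocal crosses founded from 8
    individuals per inbred strain, 125 F1 per sex per reciprocal direction,
    ~1,200 individuals per non-overlapping generation, generation-16 adults
    measured (600 females), 10% phenotypic tails of 60 flies sequenced as
    two 30-fly subpools whose reads are merged, ~70x merged depth per pool.

    ``env_sd`` is the environmental standard deviation on the scale where
    the parental strain difference is 1 trait unit; the default makes that
    difference equal 3 environmental SDs.
    """

    founders_per_strain: int = 8
    f1_per_reciprocal_sex: int = 125
    pop_size: int = 1200
    generations: int = 16
    measured_females: int = 600
    tail_fraction: float = 0.10
    read_depth: float = 70.0
    pools_per_tail: int = 2
    env_sd: float = 1.0 / 3.0
    male_recomb: bool = False

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ConfigError("generations must be >= 2")
        if not (0 < self.tail_fraction <= 0.5):
            raise ConfigError("tail_fraction must be in (0, 0.5]")
        n_tail = self.tail_fraction * self.measured_females
        if abs(n_tail - round(n_tail)) > 1e-9 or round(n_tail) < 1:
            raise ConfigError(
                "tail_fraction * measured_females must be a positive integer"
            )
        if self.read_depth < 0:
            raise ConfigError("read_depth must be non-negative")
        if self.pools_per_tail < 1:
            raise ConfigError("pools_per_tail must be >= 1")

    @property
    def tail_n(self) -> int:
        return int(round(self.tail_fraction * self.measured_females))


@dataclass(frozen=True)
class QtlLocus:
    arm: str
    pos_bp: float
    effect_pct: float  # % of the parental strain trait difference

    def __post_init__(self) -> None:
        if self.effect_pct < 0:
            raise ConfigError("QTL effects must be non-negative")


@dataclass(frozen=True)
class QtlArchitecture:
    """Additive architecture: each E allele copy at a locus adds
    effect/2 (in units of the parental difference) to the phenotype."""

    loci: tuple[QtlLocus, ...] = ()

    @classmethod
    def null(cls) -> "QtlArchitecture":
        return cls(())

    @classmethod
    def single(cls, arm: str, pos_bp: float, effect_pct: float) -> "QtlArchitecture":
        return cls((QtlLocus(arm, pos_bp, effect_pct),))


def select_extremes(
    phenotypes: np.ndarray, design: CrossDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the largest and smallest tail_fraction of measured flies.

    Returned index arrays are ordered from most extreme inward, so the
    first half of each is the outer (0-5%) subpool.  Ties are broken by a
    seeded random jitter, making the split well defined for degenerate
    phenotype vectors.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if len(phenotypes) != design.measured_females:
        raise SimulationError(
            f"expected {design.measured_females} phenotypes, got {len(phenotypes)}"
        )
    n = design.tail_n
    order = np.lexsort((rng.random(len(phenotypes)), phenotypes))
    small = order[:n]
    large = order[-n:][::-1]
    return large, small


def sample_pool_reads(
    subpool_freqs: np.ndarray,
    depth: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequence pooled DNA: per site and subpool, total reads are
    Poisson(depth / n_subpools) and large-parent-allele reads are
    Binomial(total, subpool frequency); subpool reads are merged.

    ``subpool_freqs`` has shape (n_subpools, n_sites) (a 1-D array is one
    pool).  Returns (allele_reads, total_reads) per site; a site can draw
    zero total reads, in which case it is unusable downstream.
    """
    f = np.atleast_2d(np.asarray(subpool_freqs, dtype=float))
    if np.any((f < 0) | (f > 1)):
        raise ConfigError("pool frequencies must lie in [0, 1]")
    if depth < 0:
        raise ConfigError("read depth must be non-negative")
    per = depth / f.shape[0]
    totals = rng.poisson(per, f.shape)
    reads = rng.binomial(totals, f)
    return reads.sum(axis=0), totals.sum(axis=0)


@dataclass
class SimResult:
    """Outcome of one simulated cross."""

    design: CrossDesign
    arch: QtlArchitecture
    grid: WindowGrid
    snps_per_window: int
    phenotypes: np.ndarray
    large_rows: np.ndarray
    small_rows: np.ndarray
    truth_freq_large: np.ndarray   # true E-ancestry frequency per window
    truth_freq_small: np.ndarray
    reads_large: np.ndarray        # merged E-allele reads per window
    totals_large: np.ndarray
    reads_small: np.ndarray
    totals_small: np.ndarray
    ad: np.ndarray                 # window ancestry difference (read-based)
    _bits: np.ndarray = field(repr=False, default=None)

    def arm_ad(self, arm: str) -> np.ndarray:
        lay = self.grid.layout(arm)
        return self.ad[lay.bit0 : lay.bit0 + lay.n_windows]

    def arm_max(self) -> dict[str, float]:
        return {a: float(np.nanmax(np.abs(self.arm_ad(a)))) for a in self.grid.arm_names}

    def genome_max(self) -> float:
        return float(np.nanmax(np.abs(self.ad)))

    def profile(self) -> pd.DataFrame:
        """Windowed ancestry-difference profile as a tidy table."""
        df = self.grid.to_frame()
        df["n_sites"] = self.snps_per_window
        df["ad"] = self.ad
        return df

    def truth(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["freq_large"] = self.truth_freq_large
        df["freq_small"] = self.truth_freq_small
        return df

    def mosaics(self):
        """Measured females as breakpoint-list mosaics (needs keep_cohort)."""
        if self._bits is None:
            raise ValueError("cohort not retained; rerun with keep_cohort=True")
        return engine.cohort_to_mosaics(self._bits, self.grid)


def _phenotypes(
    bits: np.ndarray,
    grid: WindowGrid,
    arch: QtlArchitecture,
    env_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = bits.shape[0]
    pheno = rng.normal(0.0, env_sd, n)
    for locus in arch.loci:
        win = grid.nearest_window(locus.arm, locus.pos_bp)
        copies = engine.genotype_at(bits, grid, locus.arm, win)
        pheno += copies * (locus.effect_pct / 100.0) / 2.0
    return pheno


def simulate_cross(
    design: CrossDesign,
    arch: QtlArchitecture = QtlArchitecture.null(),
    grid: WindowGrid | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snps_per_window: int = 50,
    keep_cohort: bool = False,
) -> SimResult:
    """Run the full cross and sequencing model once.

    Window read counts aggregate ``snps_per_window`` fixed-difference SNPs
    per window (each at Poisson(read_depth) coverage split across the
    subpools), which is distributionally equivalent to per-site sampling
    followed by the within-window average at these depths.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if grid is None:
        grid = WindowGrid.default()
    for locus in arch.loci:
        lay = grid.layout(locus.arm)
        if not (0 <= locus.pos_bp <= lay.arm.length_bp):
            raise ConfigError(f"QTL at {locus.arm}:{locus.pos_bp} outside the arm")

    packed = engine.run_population(design, grid, rng)
    n_f = len(packed)
    if design.measured_females > n_f:
        raise SimulationError(
            f"cannot measure {design.measured_females} females from a cohort of {n_f}"
        )
    bits = engine.unpack_cohort(packed, grid)
    if design.measured_females < n_f:
        keep = rng.choice(n_f, design.measured_females, replace=False)
        bits = bits[keep]

    pheno = _phenotypes(bits, grid, arch, design.env_sd, rng)
    large, small = select_extremes(pheno, design, rng)

    s = design.pools_per_tail
    large_sub = np.array_split(large, s)
    small_sub = np.array_split(small, s)
    f_large = np.stack([engine.marker_frequency(bits, g) for g in large_sub])
    f_small = np.stack([engine.marker_frequency(bits, g) for g in small_sub])

    window_depth = design.read_depth * snps_per_window
    reads_l, tot_l = sample_pool_reads(f_large, window_depth, rng)
    reads_s, tot_s = sample_pool_reads(f_small, window_depth, rng)

    with np.errstate(invalid="ignore"):
        ad = reads_l / np.where(tot_l > 0, tot_l, np.nan) - reads_s / np.where(
            tot_s > 0, tot_s, np.nan
        )

    return SimResult(
        design=design,
        arch=arch,
        grid=grid,
        snps_per_window=snps_per_window,
        phenotypes=pheno,
        large_rows=large,
        small_rows=small,
        truth_freq_large=engine.marker_frequency(bits, large),
        truth_freq_small=engine.marker_frequency(bits, small),
        reads_large=reads_l,
        totals_large=tot_l,
        reads_small=reads_s,
        totals_small=tot_s,
        ad=ad,
        _bits=bits if keep_cohort else None,
    )
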