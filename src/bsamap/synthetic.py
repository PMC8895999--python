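"""Synthetic data generators.

Everything the pipeline consumes can be generated here: SNP positions and
genetic maps, parental site tables with a controllable mix of fixed
differences, residual heterozygosity and low-difference (filterable) sites,
two-population haplotype panels with optional localized hard/soft sweeps,
gene annotations, gene-to-GO maps, and sync files produced by the forward
cross simulator.

All generators are deterministic under a fixed seed.  Compositional
fractions are honoured by exact count (deterministic rounding), not
Bernoulli sampling, so small fixtures have predictable makeup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross import SimResult
from .errors import ConfigError
from .formats import SyncSite
from .genome import DEFAULT_ARMS, Arm
from .popgen import HaplotypePanel


@dataclass(frozen=True)
class GenomeConfig:
    arms: tuple[Arm, ...] = DEFAULT_ARMS
    snps_per_arm: int = 1000

    def __post_init__(self) -> None:
        if self.snps_per_arm < 1:
            raise ConfigError("snps_per_arm must be >= 1")


def _distinct_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    if n > length:
        raise ConfigError(f"cannot place {n} distinct SNPs on a {length} bp arm")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, n, replace=False))


def gen_genome(config: GenomeConfig, seed: int | None = None) -> dict[str, np.ndarray]:
    """Uniform-random distinct SNP positions per arm (strictly increasing);
    the genetic map is the linear bp->cM map carried by each Arm."""
    rng = np.random.default_rng(seed)
    return {
        arm.name: _distinct_positions(rng, arm.length_bp, config.snps_per_arm)
        for arm in config.arms
    }


def gen_parental_pair(
    positions: dict[str, np.ndarray],
    fixed_diff_fraction: float = 0.8,
    residual_het: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Parental site table (arm, pos, p_L, p_S).

    Exact counts: round(fixed_diff_fraction * n) sites are fixed differences
    (|p_L - p_S| = 1), round(residual_het * n) sites have one parent
    heterozygous (0.5, |diff| = 0.5), and the remainder differ by < 0.25 so
    the parental-difference filter drops them.
    """
    if not (0 <= fixed_diff_fraction <= 1 and 0 <= residual_het <= 1):
        raise ConfigError("fractions must lie in [0, 1]")
    if fixed_diff_fraction + residual_het > 1:
        raise ConfigError("fixed_diff_fraction + residual_het must be <= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for arm in positions:
        frames.append(pd.DataFrame({"arm": arm, "pos": positions[arm]}))
    df = pd.concat(frames, ignore_index=True)
    n = len(df)
    n_fix = int(round(fixed_diff_fraction * n))
    n_het = int(round(residual_het * n))
    if n_fix + n_het > n:
        n_het = n - n_fix
    roles = np.zeros(n, dtype=int)  # 0 = low-difference, 1 = fixed, 2 = residual het
    order = rng.permutation(n)
    roles[order[:n_fix]] = 1
    roles[order[n_fix : n_fix + n_het]] = 2

    p_L = np.empty(n)
    p_S = np.empty(n)
    fix = roles == 1
    p_L[fix], p_S[fix] = 1.0, 0.0
    het = roles == 2
    het_parent_large = rng.random(het.sum()) < 0.5
    other = np.where(rng.random(het.sum()) < 0.5, 1.0, 0.0)
    p_L[het] = np.where(het_parent_large, 0.5, other)
    p_S[het] = np.where(het_parent_large, other, 0.5)
    low = roles == 0
    base = rng.uniform(0, 1, low.sum())
    delta = rng.uniform(-0.249, 0.249, low.sum())
    p_L[low] = np.clip(base + delta / 2, 0, 1)
    p_S[low] = np.clip(base - delta / 2, 0, 1)

    df["p_L"] = p_L
    df["p_S"] = p_S
    return df


# ---------------------------------------------------------------------------
# haplotype panels


def gen_panels(
    positions: dict[str, np.ndarray],
    n1: int,
    n2: int,
    arms: tuple[Arm, ...] = DEFAULT_ARMS,
    sweep: tuple[str, float, float, str] | None = None,
    sweep_pop: str = "pop1",
    fst: float = 0.05,
    spectrum=(0.2, 0.2),
    seed: int | None = None,
    labels=("pop1", "pop2"),
) -> HaplotypePanel:
    """Two-population panels with a shared U-shaped frequency spectrum,
    modest background differentiation, and an optional localized sweep.

    Background: per site an ancestral frequency p ~ Beta(*spectrum*), then
    population frequencies from the Balding-Nichols drift model at
    divergence ``fst`` (identical when fst = 0), then Bernoulli haplotypes.

    ``sweep`` = (arm, center bp, width bp, "hard" | "soft") in
    ``sweep_pop``: *hard* sets every swept haplotype to one core haplotype
    across the span; *soft* splits them between two cores that differ at
    half the span sites.  At the center-most site the swept allele is 1 and
    is forced to be the minor allele of the other population (a locally
    adaptive variant rare in the source population), so single-SNP
    differentiation at the center is high in both modes.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigError("need at least 2 haplotypes per population")
    if sweep_pop not in ("pop1", "pop2"):
        raise ConfigError("sweep_pop must be 'pop1' or 'pop2'")
    rng = np.random.default_rng(seed)
    by_name = {a.name: a for a in arms}
    out_pos: dict[str, np.ndarray] = {}
    pop1: dict[str, np.ndarray] = {}
    pop2: dict[str, np.ndarray] = {}
    for arm_name, pos in positions.items():
        pos = np.asarray(pos)
        s = len(pos)
        p = rng.beta(spectrum[0], spectrum[1], s)
        if fst > 0:
            pc = np.clip(p, 1e-3, 1 - 1e-3)
            a = pc * (1 - fst) / fst
            b = (1 - pc) * (1 - fst) / fst
            f1 = rng.beta(a, b)
            f2 = rng.beta(a, b)
        else:
            f1 = f2 = p
        h1 = (rng.random((n1, s)) < f1).astype(np.uint8)
        h2 = (rng.random((n2, s)) < f2).astype(np.uint8)
        if sweep is not None and sweep[0] == arm_name:
            _, center, width, mode = sweep
            arm = by_name[arm_name]
            if not (0 <= center - width / 2 and center + width / 2 <= arm.length_bp):
                raise ConfigError("sweep span extends outside the arm")
            span = np.nonzero((pos >= center - width / 2) & (pos <= center + width / 2))[0]
            if len(span):
                swept, source = (h1, h2) if sweep_pop == "pop1" else (h2, h1)
                core = (rng.random(len(span)) < f1[span]).astype(np.uint8)
                c_local = int(np.argmin(np.abs(pos[span] - center)))
                core[c_local] = 1
                if mode == "hard":
                    swept[:, span] = core
                elif mode == "soft":
                    core2 = core.copy()
                    flip = rng.random(len(span)) < 0.5
                    core2[flip] = 1 - core2[flip]
                    core2[c_local] = 1
                    take2 = rng.random(swept.shape[0]) < 0.5
                    swept[:, span] = np.where(take2[:, None], core2, core)
                else:
                    raise ConfigError(f"unknown sweep mode {mode!r}")
                # swept allele rare in the source population at the center
                c_global = span[c_local]
                src_freq = source[:, c_global].mean()
                if src_freq > 0.5:
                    source[:, c_global] = 1 - source[:, c_global]
        out_pos[arm_name] = pos
        pop1[arm_name] = h1
        pop2[arm_name] = h2
    used = tuple(by_name[a] for a in out_pos)
    return HaplotypePanel(used, out_pos, pop1, pop2, labels=tuple(labels))


# ---------------------------------------------------------------------------
# annotations


def gen_annotation(
    arms: tuple[Arm, ...],
    genes_per_arm: int = 50,
    terms: int = 20,
    mean_genes_per_term: float = 10.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Non-overlapping gene spans tiled with random gaps, plus a gene-to-GO
    map whose term sizes are Poisson(mean_genes_per_term), floored at 1."""
    if genes_per_arm < 1:
        raise ConfigError("genes_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for arm in arms:
        slot = arm.length_bp // genes_per_arm
        if slot < 10:
            raise ConfigError(
                f"{genes_per_arm} genes cannot fit on arm {arm.name} "
                f"({arm.length_bp} bp)"
            )
        for i in range(genes_per_arm):
            lo = i * slot
            a, b = np.sort(rng.integers(0, slot, size=2))
            if b == a:
                b = a + 1
            rows.append(
                (
                    f"{arm.name}_g{i}",
                    arm.name,
                    int(lo + a + 1),
                    int(lo + b + 1),
                    rng.choice(["+", "-"]),
                )
            )
    genes = pd.DataFrame(rows, columns=["gene_id", "arm", "start", "end", "strand"])
    go: dict[str, set[str]] = {}
    ids = genes["gene_id"].to_numpy()
    for t in range(terms):
        term = f"GO:{t + 1:07d}"
        size = max(1, min(len(ids), int(rng.poisson(mean_genes_per_term))))
        for g in rng.choice(ids, size, replace=False):
            go.setdefault(str(g), set()).add(term)
    return genes, go


# ---------------------------------------------------------------------------
# sync output of simulated crosses


def sync_from_sim(
    sim: SimResult,
    sites: pd.DataFrame,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    parent_depth: float | None = None,
) -> tuple[list[SyncSite], list[SyncSite]]:
    """Render a simulated cross as sync files at the given parental sites.

    Returns (pool_sites, parent_sites): the first has two pools (large,
    small), the second the two parental strains sequenced as pools.  The
    tracked allele of each site is written as the reference base 'A' and the
    alternative as 'T'.  Per site the pool frequency of the tracked allele
    is f_E * p_L + (1 - f_E) * p_S with f_E the pool's ancestry frequency
    at the site's window, and reads are Poisson/binomial as in sequencing.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    depth = sim.design.read_depth
    if parent_depth is None:
        parent_depth = depth
    grid = sim.grid
    pool_sites: list[SyncSite] = []
    par_sites: list[SyncSite] = []
    for row in sites.itertuples():
        w = grid.nearest_window(row.arm, row.pos)
        lay = grid.layout(row.arm)
        fe_l = sim.truth_freq_large[lay.bit0 + w]
        fe_s = sim.truth_freq_small[lay.bit0 + w]
        pools = []
        for fe in (fe_l, fe_s):
            f = fe * row.p_L + (1 - fe) * row.p_S
            tot = rng.poisson(depth)
            a = rng.binomial(tot, f)
            pools.append((int(a), int(tot - a), 0, 0, 0, 0))
        pool_sites.append(SyncSite(row.arm, int(row.pos), "A", tuple(pools)))
        parents = []
        for pfreq in (row.p_L, row.p_S):
            tot = rng.poisson(parent_depth)
            a = rng.binomial(tot, pfreq)
            parents.append((int(a), int(tot - a), 0, 0, 0, 0))
        par_sites.append(SyncSite(row.arm, int(row.pos), "A", tuple(parents)))
    return pool_sites, par_sites
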