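"""Vectorized forward simulator of the interbreeding population.

Tracks ancestry (E=1 / Z=0) of every homolog at one marker per window
midpoint, bit-packed per arm (arms padded to byte boundaries).  Crossovers
between adjacent markers are composed by parity, so the marker-grid process
is the exact projection of the continuous mosaic process of
:mod:`bsamap.mosaic` onto window midpoints.

Conventions: equal sex ratio every generation; mothers and fathers drawn
uniformly with replacement (Wright-Fisher); females recombine, males do not
(achiasmy) and transmit one intact homolog per arm; the X is maternal-only
in sons and paternal X goes to daughters.
"""

from __future__ import annotations

import numpy as np

from .genome import WindowGrid
from .errors import SimulationError

# packbits is MSB-first: marker (byte*8 + j) is bit 7-j of the byte.
_TAIL = np.array([0xFF >> i for i in range(8)], dtype=np.uint8)


def _crossover_masks(rng: np.random.Generator, n: int, grid: WindowGrid) -> np.ndarray:
    """Template-choice masks for ``n`` female meioses: bit m of row i says
    which maternal homolog supplies marker m.  Poisson(cM/100) crossovers
    per arm, uniform in bp (linear map), independent random phase per arm."""
    H = np.zeros((n, grid.n_bytes), dtype=np.uint8)
    for lay in grid.layouts:
        lam = lay.arm.length_cm / 100.0
        if lam > 0:
            k = rng.poisson(lam, n)
            tot = int(k.sum())
            if tot:
                rows = np.repeat(np.arange(n), k)
                midx = np.searchsorted(lay.mids, rng.uniform(0.0, lay.arm.length_bp, tot))
                inside = midx < lay.n_windows  # a crossover past the last marker flips nothing
                rows, midx = rows[inside], midx[inside]
                b = lay.byte0 + (midx >> 3)
                r = midx & 7
                for i in range(len(rows)):
                    H[rows[i], b[i]] ^= _TAIL[r[i]]
                    H[rows[i], b[i] + 1 : lay.byte1] ^= 0xFF
        phase = (rng.integers(0, 2, n) * 0xFF).astype(np.uint8)
        H[:, lay.byte0 : lay.byte1] ^= phase[:, None]
    return H


def _next_generation(
    rng: np.random.Generator,
    females: np.ndarray,
    males: np.ndarray,
    grid: WindowGrid,
    n_f: int,
    n_m: int,
    male_recomb: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    if len(females) < 1 or len(males) < 1:
        raise SimulationError("population collapsed: a sex has no individuals")
    n = n_f + n_m
    mom = rng.integers(0, len(females), n)
    dad = rng.integers(0, len(males), n)
    H = _crossover_masks(rng, n, grid)
    maternal = (females[mom, 0] & ~H) | (females[mom, 1] & H)
    if male_recomb:
        H2 = _crossover_masks(rng, n, grid)
        paternal = (males[dad, 0] & ~H2) | (males[dad, 1] & H2)
    else:
        paternal = np.empty((n, grid.n_bytes), dtype=np.uint8)
        sires = males[dad]
        for lay in grid.layouts:
            pick = rng.integers(0, 2, n).astype(bool)
            sl = slice(lay.byte0, lay.byte1)
            paternal[:, sl] = np.where(pick[:, None], sires[:, 1, sl], sires[:, 0, sl])
    offspring = np.stack([maternal, paternal], axis=1)
    new_f = np.ascontiguousarray(offspring[:n_f])
    new_m = np.ascontiguousarray(offspring[n_f:])
    # sons: X is maternal-only; mirror it into the second slot so either
    # slot reads the single X (the duplicate is never double-transmitted)
    x = next((lay for lay in grid.layouts if lay.arm.name == "X"), None)
    if x is not None:
        new_m[:, 1, x.byte0 : x.byte1] = new_m[:, 0, x.byte0 : x.byte1]
    return new_f, new_m


def founder_f1(grid: WindowGrid, n_per_sex: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed F1 cohorts of a reciprocal cross between fully inbred strains:
    everything heterozygous E/Z; F1 males split evenly between E and Z
    hemizygous X by reciprocal direction."""
    females = np.zeros((n_per_sex, 2, grid.n_bytes), dtype=np.uint8)
    females[:, 0, :] = 0xFF
    males = np.zeros((n_per_sex, 2, grid.n_bytes), dtype=np.uint8)
    males[:, 0, :] = 0xFF
    x = next((lay for lay in grid.layouts if lay.arm.name == "X"), None)
    if x is not None:
        half = n_per_sex // 2
        males[half:, 0, x.byte0 : x.byte1] = 0x00
        males[:, 1, x.byte0 : x.byte1] = males[:, 0, x.byte0 : x.byte1]
    return females, males


def run_population(
    design,
    grid: WindowGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    """Breed the cross forward and return the final female cohort, packed
    (n_females, 2 homologs, grid.n_bytes)."""
    if design.pop_size < 2:
        raise SimulationError("pop_size must be >= 2")
    n_f = design.pop_size // 2
    n_m = design.pop_size - n_f
    females, males = founder_f1(grid, design.f1_per_reciprocal_sex * 2)
    for _ in range(design.generations - 1):
        females, males = _next_generation(
            rng, females, males, grid, n_f, n_m, design.male_recomb
        )
    return females


def unpack_cohort(packed: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Unpack to ancestry indicators (n, 2, grid.n_windows) uint8, dropping
    the per-arm padding bits."""
    bits = np.unpackbits(packed, axis=-1)
    cols = np.concatenate(
        [np.arange(lay.byte0 * 8, lay.byte0 * 8 + lay.n_windows) for lay in grid.layouts]
    )
    return bits[..., cols]


def marker_frequency(bits: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """E-ancestry frequency per marker among the selected diploid rows."""
    return bits[rows].mean(axis=(0, 1))


def genotype_at(bits: np.ndarray, grid: WindowGrid, arm: str, window: int) -> np.ndarray:
    """Per-individual count of E alleles (0/1/2) at one marker."""
    lay = grid.layout(arm)
    col = lay.bit0 + window
    return bits[:, :, col].sum(axis=1)


def cohort_to_mosaics(bits: np.ndarray, grid: WindowGrid, sexes=None):
    """Convert unpacked marker ancestries to block-list mosaics.

    Breakpoints are placed at window boundaries between differing adjacent
    markers, so the mosaics are the coarsest block structure consistent
    with the marker grid.
    """
    from .mosaic import GenomeMosaic, Homolog

    out = []
    n = bits.shape[0]
    for i in range(n):
        homs = {}
        for lay in grid.layouts:
            sl = slice(lay.bit0, lay.bit0 + lay.n_windows)
            pair = []
            for h in range(2):
                v = bits[i, h, sl]
                flips = np.nonzero(np.diff(v) != 0)[0]
                # boundary between windows j and j+1
                pair.append(Homolog(start=int(v[0]), breaks=lay.ends[flips].astype(float)))
            sex = "F" if sexes is None else sexes[i]
            if sex == "M" and lay.arm.name == "X":
                pair = pair[:1]
            homs[lay.arm.name] = tuple(pair)
        out.append(GenomeMosaic(homologs=homs, sex="F" if sexes is None else sexes[i]))
    return out
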