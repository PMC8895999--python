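"""Ancestry-mosaic genomes and meiosis.

An individual's genome is a set of homologs per arm, each a run-length list
of ancestry blocks (Ethiopia-derived ``E`` = 1 or Zambia-derived ``Z`` = 0).
Female meiosis draws per-arm crossover counts Poisson(cM/100) with
uniform-in-cM placement and no interference; male meiosis performs no
recombination (Drosophila achiasmy) and transmits one intact homolog per
arm.  Males are hemizygous for the X and carry a single X homolog.

This representation is exact (no marker discretization) and is used for
small-scale simulation and as the reference semantics for the vectorized
population engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Arm

E = 1  #: Ethiopia (large-parent) ancestry
Z = 0  #: Zambia (small-parent) ancestry


@dataclass
class Homolog:
    """One chromosome copy: ancestry switches at ``breaks`` (bp, ascending,
    exclusive of arm ends); ancestry left of the first break is ``start``."""

    start: int
    breaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def ancestry_at(self, pos) -> np.ndarray:
        """Ancestry (0/1) at physical position(s)."""
        n_left = np.searchsorted(self.breaks, np.asarray(pos, dtype=float), side="right")
        return (self.start + n_left) % 2

    def blocks(self, length_bp: float) -> list[tuple[float, float, int]]:
        """(start, end, ancestry) tiles covering [0, length_bp)."""
        edges = np.concatenate(([0.0], self.breaks, [float(length_bp)]))
        return [
            (edges[i], edges[i + 1], (self.start + i) % 2)
            for i in range(len(edges) - 1)
        ]

    @property
    def n_junctions(self) -> int:
        return len(self.breaks)


def uniform_homolog(ancestry: int) -> Homolog:
    return Homolog(start=ancestry)


@dataclass
class GenomeMosaic:
    """All homologs of one individual; males carry one X homolog."""

    homologs: dict[str, tuple[Homolog, ...]]
    sex: str  # "F" or "M"

    def validate(self, arms: dict[str, Arm]) -> None:
        for name, homs in self.homologs.items():
            expected = 1 if (self.sex == "M" and name == "X") else 2
            if len(homs) != expected:
                raise ValueError(f"{name}: expected {expected} homologs, got {len(homs)}")
            for h in homs:
                b = h.breaks
                if len(b) and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= arms[name].length_bp):
                    raise ValueError(f"{name}: breakpoints not strictly inside the arm")


def recombine(a: Homolog, b: Homolog, xover_bp: np.ndarray, start_with: int) -> Homolog:
    """Gamete homolog reading from ``a`` (start_with=0) or ``b`` (1),
    switching template at each crossover position."""
    xover_bp = np.sort(np.asarray(xover_bp, dtype=float))
    pts = np.unique(np.concatenate((a.breaks, b.breaks, xover_bp)))
    # evaluate ancestry on each segment at its left edge
    seg_left = np.concatenate(([0.0], pts))
    src = (start_with + np.searchsorted(xover_bp, seg_left, side="right")) % 2
    anc_a = a.ancestry_at(seg_left)
    anc_b = b.ancestry_at(seg_left)
    anc = np.where(src == 0, anc_a, anc_b)
    keep = np.nonzero(np.diff(anc) != 0)[0]
    return Homolog(start=int(anc[0]), breaks=pts[keep])


def meiosis(
    parent: GenomeMosaic,
    arms: tuple[Arm, ...],
    rng: np.random.Generator,
) -> dict[str, Homolog]:
    """One gamete from ``parent``.

    Females: Poisson(cM/100) crossovers per arm, uniform in cM (uniform in
    bp under the linear map).  Males: no recombination; one intact homolog
    per arm chosen at random, the single X if hemizygous.  A 0 cM arm never
    recombines.
    """
    gamete: dict[str, Homolog] = {}
    for arm in arms:
        homs = parent.homologs[arm.name]
        if parent.sex == "M":
            gamete[arm.name] = homs[int(rng.integers(len(homs)))]
            continue
        a, b = homs
        k = rng.poisson(arm.length_cm / 100.0)
        start = int(rng.integers(2))
        if k == 0:
            gamete[arm.name] = (a, b)[start]
        else:
            xo = rng.uniform(0.0, arm.length_bp, size=k)
            gamete[arm.name] = recombine(a, b, xo, start)
    return gamete


def f1_mosaic(sex: str, maternal_x: int, arms: tuple[Arm, ...]) -> GenomeMosaic:
    """An F1 individual of a cross between fully inbred E and Z strains:
    heterozygous E/Z on all arms; F1 males carry the maternal X only."""
    homs: dict[str, tuple[Homolog, ...]] = {}
    for arm in arms:
        if sex == "M" and arm.name == "X":
            homs[arm.name] = (uniform_homolog(maternal_x),)
        else:
            homs[arm.name] = (uniform_homolog(E), uniform_homolog(Z))
    return GenomeMosaic(homologs=homs, sex=sex)
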