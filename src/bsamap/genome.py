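"""Genome layout: chromosome arms, genetic maps and window grids.

The five euchromatic arms of *Drosophila melanogaster* (X, 2L, 2R, 3L, 3R)
are the default coordinate system.  Physical lengths are release-5-like and
female genetic lengths give realistic recombination densities; both are
configurable.  Positions are 1-based inclusive base pairs throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class Arm:
    """One chromosome arm with a linear genetic map."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ConfigError(f"arm {self.name!r} has non-positive length")
        if self.length_cm < 0:
            raise ConfigError(f"arm {self.name!r} has negative genetic length")

    def bp_to_cm(self, bp):
        """Cumulative map position (cM) at a physical coordinate, linear map."""
        return np.asarray(bp, dtype=float) / self.length_bp * self.length_cm

    def cm_to_bp(self, cm):
        if self.length_cm == 0:
            raise ConfigError(f"arm {self.name!r} has a 0 cM map; cM coordinates undefined")
        return np.asarray(cm, dtype=float) / self.length_cm * self.length_bp


#: Default arm set: X, 2L, 2R, 3L, 3R with ~23/23/21/24.5/27.9 Mb and
#: female map lengths ~66/55/52/47/56 cM.
DEFAULT_ARMS: tuple[Arm, ...] = (
    Arm("X", 23_000_000, 66.0),
    Arm("2L", 23_000_000, 55.0),
    Arm("2R", 21_000_000, 52.0),
    Arm("3L", 24_500_000, 47.0),
    Arm("3R", 27_900_000, 56.0),
)

#: SNP-density window counts per arm used by the original scans
#: (2,728 / 3,131 / 2,357 / 2,956 / 2,935; ~8.4 kb each on average).
DEFAULT_WINDOW_COUNTS: dict[str, int] = {
    "X": 2728,
    "2L": 3131,
    "2R": 2357,
    "3L": 2956,
    "3R": 2935,
}

AUTOSOMES: tuple[str, ...] = ("2L", "2R", "3L", "3R")


@dataclass
class ArmLayout:
    """Per-arm window layout plus the bit/byte addressing used by the
    population engine (each arm is padded to a byte boundary so packed
    homolog arrays never share bytes across arms)."""

    arm: Arm
    n_windows: int
    mids: np.ndarray        # window midpoints, bp
    starts: np.ndarray      # window start bounds, bp (1-based)
    ends: np.ndarray        # window end bounds, bp (inclusive)
    bit0: int = 0
    byte0: int = 0
    byte1: int = 0


class WindowGrid:
    """An ordered set of genomic windows over a fixed arm set.

    Serves two roles: the windowing scheme for ancestry-difference profiles,
    and the marker grid at which the forward simulator tracks ancestry (one
    marker per window midpoint).
    """

    def __init__(self, arms: tuple[Arm, ...], counts: dict[str, int]):
        self.arms = tuple(arms)
        self.layouts: list[ArmLayout] = []
        byte_off = 0
        bit_off = 0
        for arm in self.arms:
            m = int(counts[arm.name])
            if m < 1:
                raise ConfigError(f"arm {arm.name!r}: window count must be >= 1")
            edges = np.linspace(0, arm.length_bp, m + 1)
            mids = (edges[:-1] + edges[1:]) / 2.0
            starts = np.floor(edges[:-1]).astype(np.int64) + 1
            ends = np.floor(edges[1:]).astype(np.int64)
            lay = ArmLayout(arm, m, mids, starts, ends)
            lay.bit0 = bit_off
            lay.byte0 = byte_off
            lay.byte1 = byte_off + (m + 7) // 8
            byte_off = lay.byte1
            bit_off += m
            self.layouts.append(lay)
        self.n_bytes = byte_off
        self.n_windows = bit_off
        self._by_name = {lay.arm.name: lay for lay in self.layouts}

    @classmethod
    def default(cls) -> "WindowGrid":
        return cls(DEFAULT_ARMS, DEFAULT_WINDOW_COUNTS)

    @classmethod
    def evenly_spaced(cls, arms: tuple[Arm, ...], windows_per_arm: int) -> "WindowGrid":
        return cls(arms, {a.name: windows_per_arm for a in arms})

    def layout(self, arm_name: str) -> ArmLayout:
        return self._by_name[arm_name]

    @property
    def arm_names(self) -> list[str]:
        return [lay.arm.name for lay in self.layouts]

    def to_frame(self) -> pd.DataFrame:
        """Window table: arm, win (index within arm), start, end, mid."""
        rows = []
        for lay in self.layouts:
            rows.append(
                pd.DataFrame(
                    {
                        "arm": lay.arm.name,
                        "win": np.arange(lay.n_windows),
                        "start": lay.starts,
                        "end": lay.ends,
                        "mid": lay.mids,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def nearest_window(self, arm_name: str, pos: float) -> int:
        lay = self.layout(arm_name)
        i = int(np.searchsorted(lay.mids, pos))
        if i == 0:
            return 0
        if i >= lay.n_windows:
            return lay.n_windows - 1
        return i if abs(lay.mids[i] - pos) < abs(pos - lay.mids[i - 1]) else i - 1
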