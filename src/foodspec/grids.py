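"""Solvent-specific chemical-shift bin grids.

A binned spectrum lives on a fixed per-solvent grid: 716 bins over
0.5-9.0 ppm for D2O extracts, 547 bins over 0.5-7.0 ppm for CDCl3
extracts.  The grid is defined by (n_bins, shift_min, shift_max); the
bin width follows as (shift_max - shift_min) / n_bins and bins are
half-open intervals labeled by their centers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["Solvent", "BinGrid", "GRIDS", "grid_for", "GridMismatchError"]


class GridMismatchError(ValueError):
    """A chemical shift or spectrum does not fit the expected bin grid."""


class Solvent(str, enum.Enum):
    """Deuterated extraction solvent; each defines a spectrum partition."""

    D2O = "D2O"
    CDCL3 = "CDCl3"

    @classmethod
    def parse(cls, text: "str | Solvent") -> "Solvent":
        if isinstance(text, Solvent):
            return text
        key = str(text).strip().lower().replace("_", "")
        if key in ("d2o", "d2o)"):
            return cls.D2O
        if key in ("cdcl3",):
            return cls.CDCL3
        raise ValueError(f"unknown solvent {text!r}; expected 'D2O' or 'CDCl3'")


@dataclass(frozen=True)
class BinGrid:
    """Equal-width chemical-shift axis for one solvent partition."""

    solvent: Solvent
    n_bins: int
    shift_min: float
    shift_max: float

    def __post_init__(self) -> None:
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        if not self.shift_min < self.shift_max:
            raise ValueError("shift_min must be below shift_max")

    @property
    def bin_width(self) -> float:
        return (self.shift_max - self.shift_min) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        """Bin centers in ppm, strictly increasing."""
        w = self.bin_width
        return self.shift_min + (np.arange(self.n_bins) + 0.5) * w

    def index_of(self, shift: float) -> int:
        """Grid index whose center is within half a bin width of *shift*.

        Raises GridMismatchError for shifts outside the grid range.
        """
        w = self.bin_width
        eps = 1e-9 * max(1.0, abs(shift))
        if shift < self.shift_min - w / 2 - eps or shift > self.shift_max + w / 2 + eps:
            raise GridMismatchError(
                f"chemical shift {shift} ppm outside {self.solvent.value} grid "
                f"[{self.shift_min}, {self.shift_max}] ppm"
            )
        idx = int(np.clip(np.floor((shift - self.shift_min) / w), 0, self.n_bins - 1))
        if abs(shift - self.centers[idx]) > w / 2 + eps:
            raise GridMismatchError(
                f"chemical shift {shift} ppm matches no {self.solvent.value} grid bin"
            )
        return idx


GRIDS: dict[Solvent, BinGrid] = {
    Solvent.D2O: BinGrid(Solvent.D2O, 716, 0.5, 9.0),
    Solvent.CDCL3: BinGrid(Solvent.CDCL3, 547, 0.5, 7.0),
}


def grid_for(solvent: "str | Solvent") -> BinGrid:
    """Return the canonical grid for a solvent ('D2O' or 'CDCl3')."""
    return GRIDS[Solvent.parse(solvent)]
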