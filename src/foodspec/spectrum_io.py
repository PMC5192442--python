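"""Reader/writer for the two-column binned-spectrum text format.

Each row of the file is ``<chemical shift>\\t<intensity>``.  A D2O file
must contain exactly 716 rows and a CDCl3 file exactly 547; rows may
appear in any order (ascending or descending ppm) and are matched to
grid bins by chemical shift within half a bin width.  Lines starting
with ``#`` and blank lines are ignored.  Negative intensities are
clamped to zero with a logged warning (phasing artifacts on bench-top
instruments).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .grids import BinGrid, GridMismatchError, Solvent, grid_for

__all__ = [
    "BinnedSpectrum",
    "SpectrumFormatError",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
]

logger = logging.getLogger(__name__)


class SpectrumFormatError(ValueError):
    """Wrong row count or structural problem in a binned-spectrum file."""


class SpectrumParseError(ValueError):
    """Non-numeric or malformed field in a binned-spectrum file."""


@dataclass
class BinnedSpectrum:
    """Intensities on a solvent bin grid, plus provenance metadata.

    ``normalized`` marks spectra that have been through the full
    preprocessing pipeline; ``norm_factor`` stores the normalizing sum
    so the raw scale can be recovered.
    """

    grid: BinGrid
    intensities: np.ndarray
    name: str = ""
    tags: list[str] = field(default_factory=list)
    normalized: bool = False
    norm_factor: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=np.float64)
        if v.ndim != 1 or v.shape[0] != self.grid.n_bins:
            raise SpectrumFormatError(
                f"expected {self.grid.n_bins} intensities for "
                f"{self.grid.solvent.value}, found {v.shape[0] if v.ndim == 1 else v.shape}"
            )
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        self.intensities = v

    def replace(self, intensities: np.ndarray, **meta) -> "BinnedSpectrum":
        kw = dict(
            grid=self.grid,
            intensities=intensities,
            name=self.name,
            tags=list(self.tags),
            normalized=self.normalized,
            norm_factor=self.norm_factor,
        )
        kw.update(meta)
        return BinnedSpectrum(**kw)


def read_spectrum(path: str | os.PathLike, solvent: str | Solvent) -> BinnedSpectrum:
    """Read a binned spectrum from two-column tab-delimited text.

    Parameters
    ----------
    path:
        File with one ``shift<TAB>intensity`` row per bin.
    solvent:
        ``'D2O'`` or ``'CDCl3'``; selects the grid (716 or 547 bins).

    Raises
    ------
    SpectrumFormatError
        Row count differs from the grid's bin count, or a bin is
        duplicated / missing.
    SpectrumParseError
        A field is not numeric (reported with its line number).
    GridMismatchError
        A chemical shift matches no grid bin.
    """
    grid = grid_for(solvent)
    rows: list[tuple[float, float, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split("\t")
            if len(parts) != 2:
                parts = text.split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 tab-delimited fields, "
                    f"found {len(parts)}"
                )
            try:
                shift, intensity = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            if not (np.isfinite(shift) and np.isfinite(intensity)):
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-finite value"
                )
            rows.append((shift, intensity, lineno))

    if len(rows) != grid.n_bins:
        raise SpectrumFormatError(
            f"{path}: expected {grid.n_bins} rows for {grid.solvent.value}, "
            f"found {len(rows)}"
        )

    intensities = np.full(grid.n_bins, np.nan)
    for shift, intensity, lineno in rows:
        idx = grid.index_of(shift)
        if not np.isnan(intensities[idx]):
            raise SpectrumFormatError(
                f"{path}: line {lineno}: duplicate row for bin at "
                f"{grid.centers[idx]:.4f} ppm"
            )
        intensities[idx] = intensity
    # row count matches and no duplicates => every bin filled

    n_neg = int(np.sum(intensities < 0))
    if n_neg:
        logger.warning(
            "%s: clamped %d negative intensities to zero", path, n_neg
        )
        intensities = np.clip(intensities, 0.0, None)

    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return BinnedSpectrum(grid=grid, intensities=intensities, name=name)


def write_spectrum(spectrum: BinnedSpectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column text; round-trips to full precision."""
    centers = spectrum.grid.centers
    with open(path, "w", encoding="utf-8") as fh:
        for c, v in zip(centers, spectrum.intensities):
            fh.write(f"{c:.10g}\t{v:.17g}\n")
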