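"""Preprocessing pipeline applied before any similarity or statistics.

The pipeline is region mask -> noise filter -> normalization, applied
identically to the query and to every database spectrum it is compared
against:

* region mask: up to three user-chosen chemical-shift intervals
  (typically residual solvent peaks) are zeroed and thereby ignored by
  all downstream computation;
* noise filter: bins below max(intensity)/75 are set to zero;
* normalization: each intensity is divided by the sum of squared bin
  intensities, q_i <- q_i / sum_j q_j**2 (the ``sum_squares`` method);
  a unit-Euclidean-norm variant (``euclidean``) is available.

Masking comes first: a masked region is ignored for *all* further
computation, so a large solvent peak must set neither the max/75 noise
threshold nor the normalizing sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectrum_io import BinnedSpectrum

__all__ = [
    "RegionMask",
    "NormalizationError",
    "NOISE_FILTER_DIVISOR",
    "noise_filter",
    "apply_mask",
    "normalize",
    "preprocess",
]

#: Noise threshold is the spectrum maximum divided by this constant.
NOISE_FILTER_DIVISOR = 75.0

MAX_REGIONS = 3


class NormalizationError(ValueError):
    """Normalization undefined (spectrum all zero after filter/mask)."""


@dataclass(frozen=True)
class RegionMask:
    """Up to three [low, high] ppm intervals ignored in all computation."""

    regions: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        regions = tuple((float(lo), float(hi)) for lo, hi in self.regions)
        if len(regions) > MAX_REGIONS:
            raise ValueError(f"at most {MAX_REGIONS} masked regions allowed")
        for lo, hi in regions:
            if not lo < hi:
                raise ValueError(f"mask interval ({lo}, {hi}) must have low < high")
        object.__setattr__(self, "regions", regions)

    @classmethod
    def parse(cls, specs: "tuple[str, ...] | list[str] | None") -> "RegionMask":
        """Build a mask from ``"low:high"`` strings (CLI/config form)."""
        if not specs:
            return cls()
        regions = []
        for spec in specs:
            lo, _, hi = str(spec).partition(":")
            regions.append((float(lo), float(hi)))
        return cls(tuple(regions))

    @property
    def key(self) -> tuple:
        """Hashable identity used for preprocessed-vector caching."""
        return tuple(sorted(self.regions))

    def __bool__(self) -> bool:
        return bool(self.regions)


def noise_filter(spectrum: BinnedSpectrum) -> BinnedSpectrum:
    """Zero every bin below max(intensity)/75; idempotent."""
    if spectrum.normalized:
        raise ValueError("noise_filter must run before normalization")
    v = spectrum.intensities
    threshold = v.max() / NOISE_FILTER_DIVISOR
    return spectrum.replace(np.where(v < threshold, 0.0, v))


def apply_mask(spectrum: BinnedSpectrum, mask: "RegionMask | None") -> BinnedSpectrum:
    """Zero bins whose centers fall in any masked interval."""
    if mask is None or not mask:
        return spectrum
    centers = spectrum.grid.centers
    keep = np.ones(spectrum.grid.n_bins, dtype=bool)
    for lo, hi in mask.regions:
        if hi < spectrum.grid.shift_min or lo > spectrum.grid.shift_max:
            warnings.warn(
                f"mask region ({lo}, {hi}) ppm lies outside the "
                f"{spectrum.grid.solvent.value} grid; no effect",
                stacklevel=2,
            )
            continue
        keep &= ~((centers >= lo) & (centers <= hi))
    return spectrum.replace(np.where(keep, spectrum.intensities, 0.0))


def normalize(spectrum: BinnedSpectrum, method: str = "sum_squares") -> BinnedSpectrum:
    """Divide intensities by the sum of squared bin intensities.

    ``method='euclidean'`` divides by the square root of that sum
    instead (unit Euclidean norm).  The divisor is stored on the result
    as ``norm_factor`` so the input scale is recoverable.
    """
    if spectrum.normalized:
        raise ValueError("spectrum already normalized; pipeline applies it once")
    v = spectrum.intensities
    ss = float(np.dot(v, v))
    if ss == 0.0:
        raise NormalizationError(
            f"cannot normalize all-zero spectrum {spectrum.name!r}"
        )
    if method == "sum_squares":
        factor = ss
    elif method == "euclidean":
        factor = float(np.sqrt(ss))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return spectrum.replace(v / factor, normalized=True, norm_factor=factor)


def preprocess(
    spectrum: BinnedSpectrum,
    mask: "RegionMask | None" = None,
    method: str = "sum_squares",
) -> BinnedSpectrum:
    """Full pipeline: apply_mask -> noise_filter -> normalize."""
    return normalize(noise_filter(apply_mask(spectrum, mask)), method=method)
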