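"""Similarity computation and threshold search.

The similarity D between two preprocessed spectra is the sum of squared
per-bin differences, D = sum_i (q_i - Q_i)^2; lower means more similar
and D = 0 is a complete match.  Database spectra with D less than or
equal to the query threshold are hits.  As a rule of thumb, a threshold
of 0.1 works in sparse (fish-like) regions of a database while crowded
(vegetable-like) regions call for 0.05; the sensitivity profile makes
this judgement quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import cdist

from .database import FoodDB
from .grids import GridMismatchError
from .preprocess import RegionMask, preprocess
from .spectrum_io import BinnedSpectrum

__all__ = [
    "Hit",
    "HitSet",
    "similarity",
    "search",
    "sensitivity_profile",
    "recommend_threshold",
    "DEFAULT_THRESHOLDS",
]

#: Threshold grid used for the search-sensitivity profile.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3)


class Hit(NamedTuple):
    spectrum_id: int
    similarity: float


@dataclass
class HitSet:
    """Search result: hits sorted by ascending similarity."""

    query_name: str
    threshold: float
    hits: list[Hit] = field(default_factory=list)

    @property
    def n(self) -> int:
        """Number of hit spectra (N)."""
        return len(self.hits)

    @property
    def d_bar(self) -> float:
        """Mean similarity over the hits (D-bar); NaN when empty."""
        if not self.hits:
            return float("nan")
        return float(np.mean([h.similarity for h in self.hits]))

    @property
    def spectrum_ids(self) -> list[int]:
        return [h.spectrum_id for h in self.hits]

    def similarity_of(self, spectrum_id: int) -> float:
        for h in self.hits:
            if h.spectrum_id == spectrum_id:
                return h.similarity
        raise KeyError(f"spectrum {spectrum_id} is not a hit")


def similarity(query: BinnedSpectrum, other: BinnedSpectrum) -> float:
    """D = sum_i (q_i - Q_i)^2 on preprocessed spectra.

    Both spectra must be on the same grid and already preprocessed
    (noise filter, identical mask, normalization).
    """
    if query.grid != other.grid:
        raise GridMismatchError(
            f"cannot compare {query.grid.solvent.value} with "
            f"{other.grid.solvent.value} spectra"
        )
    if not (query.normalized and other.normalized):
        raise ValueError("similarity is defined on preprocessed spectra")
    diff = query.intensities - other.intensities
    return float(np.dot(diff, diff))


def search(
    db: FoodDB,
    query: BinnedSpectrum,
    threshold: float,
    mask: "RegionMask | None" = None,
    method: str = "sum_squares",
) -> HitSet:
    """All same-solvent database spectra with D <= threshold.

    The query's mask is applied to the database spectra as well, so the
    comparison ignores exactly the regions the user ignored.  Ties in D
    are broken by spectrum id.
    """
    if not threshold > 0:
        raise ValueError("similarity threshold must be positive")
    qp = query if query.normalized else preprocess(query, mask=mask, method=method)
    ids, matrix = db.preprocessed_matrix(query.grid.solvent, mask=mask, method=method)
    if not ids:
        return HitSet(query_name=query.name, threshold=threshold)
    diffs = matrix - qp.intensities
    d = np.einsum("ij,ij->i", diffs, diffs)
    order = sorted(
        (Hit(sid, float(dist)) for sid, dist in zip(ids, d) if dist <= threshold),
        key=lambda h: (h.similarity, h.spectrum_id),
    )
    return HitSet(query_name=query.name, threshold=threshold, hits=order)


def sensitivity_profile(
    db: FoodDB,
    solvent,
    thresholds: "tuple[float, ...]" = DEFAULT_THRESHOLDS,
    mask: "RegionMask | None" = None,
    method: str = "sum_squares",
):
    """Hit counts per threshold when every database spectrum is the query.

    Equivalent to the distribution of all pairwise distances: for each
    spectrum, counts database entries (including itself) within each
    threshold.  The first principal-component score locates each query
    on the main axis of spectral variation, so crowded regions (large
    hit counts) can be recognized and the threshold lowered there.

    Returns a DataFrame indexed by spectrum id with columns ``name``,
    ``pc1`` and one ``hits@<t>`` column per threshold.
    """
    import pandas as pd

    from .pca_summary import pca

    ids, matrix = db.preprocessed_matrix(solvent, mask=mask, method=method)
    if len(ids) < 2:
        raise ValueError("sensitivity profile needs at least 2 spectra")
    d2 = cdist(matrix, matrix, metric="sqeuclidean")
    result = pca(db, solvent, k=1, method=method)
    pc1 = dict(zip(result.spectrum_ids, result.scores[:, 0]))
    names = db.names_of(ids)
    data = {
        "name": [names[i] for i in ids],
        "pc1": [pc1.get(i, float("nan")) for i in ids],
    }
    for t in thresholds:
        data[f"hits@{t:g}"] = (d2 <= t).sum(axis=1)
    return pd.DataFrame(data, index=pd.Index(ids, name="spectrum_id"))


def recommend_threshold(
    hit_counts,
    thresholds,
    partition_size: int,
    max_fraction: float = 0.5,
) -> float:
    """Pick a search threshold from one query's sensitivity-profile row.

    A threshold is too permissive once a query hits a large share of the
    whole partition — estimates from such a hit set mix unlike spectra
    and become unreliable, so the threshold should be lowered.  Returns
    the largest threshold whose hit count stays at or below
    ``max_fraction`` of the partition, falling back to the smallest
    threshold.
    """
    counts = np.asarray(hit_counts, dtype=float)
    thresholds = list(thresholds)
    if len(counts) != len(thresholds):
        raise ValueError("one hit count per threshold required")
    budget = max_fraction * partition_size
    eligible = [t for t, c in zip(thresholds, counts) if c <= budget]
    return max(eligible) if eligible else min(thresholds)
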