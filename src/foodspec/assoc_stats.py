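"""Covariance/correlation spectra and similarity-weighted score estimates.

Given the hit set of a query and the tasting (or hardness) records
attached to the hit spectra, these statistics link spectral bins to the
scores:

* covariance spectrum: per bin i, c_i = (sum_j q_ij t_j)/P - qbar_i*tbar,
  the population covariance between bin intensity and score over the P
  feature records (a spectrum with k records contributes k pairs);
* correlation spectrum: per-bin Pearson r_i; bins with zero intensity
  variance (or zero score variance) are undefined and reported as NaN,
  never as 0;
* estimated score: A = sum_j w_j t_j / sum_j w_j with w_j =
  1/(D_j + Dbar + 1), where D_j is the similarity of the spectrum
  behind record j and Dbar the average over the P records.  When
  complete matches (D = 0) exist, their plain average over the P'
  matches is reported as well.

The unit of analysis is the feature record, not the spectrum: two
tastings by two panel volunteers on one spectrum are two (q, t) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .database import FeatureKind, FeatureRecord, FoodDB
from .grids import BinGrid
from .preprocess import RegionMask, preprocess
from .search import HitSet

__all__ = [
    "AssocSpectra",
    "ScoreEstimate",
    "covariance_spectrum",
    "correlation_spectrum",
    "association_spectra",
    "estimate_score",
]


@dataclass
class AssocSpectra:
    """Per-bin covariance and/or Pearson correlation to a feature."""

    grid: BinGrid
    feature_kind: FeatureKind
    P: int
    covariance: "np.ndarray | None" = None
    correlation: "np.ndarray | None" = None  # NaN marks undefined bins


@dataclass
class ScoreEstimate:
    """Similarity-weighted score with hit min/max and complete matches."""

    weighted_average: float
    hit_min: float
    hit_max: float
    P: int
    P_prime: int = 0
    complete_match_average: "float | None" = None

    def to_dict(self) -> dict:
        return {
            "weighted_average": self.weighted_average,
            "hit_min": self.hit_min,
            "hit_max": self.hit_max,
            "P": self.P,
            "P_prime": self.P_prime,
            "complete_match_average": self.complete_match_average,
        }


def _paired_arrays(
    hits: HitSet,
    features: "list[FeatureRecord]",
    db: FoodDB,
    mask: "RegionMask | None",
    method: str,
):
    """(Q, t) with one row of preprocessed intensities per feature record."""
    hit_ids = set(hits.spectrum_ids)
    used = [f for f in sorted(features, key=lambda f: f.id) if f.spectrum_id in hit_ids]
    if not used:
        return None, None, []
    vectors = {}
    for f in used:
        if f.spectrum_id not in vectors:
            raw = db.get_spectrum(f.spectrum_id)
            vectors[f.spectrum_id] = preprocess(raw, mask=mask, method=method).intensities
    Q = np.vstack([vectors[f.spectrum_id] for f in used])
    t = np.array([f.value for f in used], dtype=np.float64)
    return Q, t, used


def covariance_spectrum(
    hits: HitSet,
    features: "list[FeatureRecord]",
    db: FoodDB,
    mask: "RegionMask | None" = None,
    method: str = "sum_squares",
) -> "AssocSpectra | None":
    """Population covariance per bin; None when no feature pairs exist."""
    Q, t, used = _paired_arrays(hits, features, db, mask, method)
    if Q is None:
        return None
    P = len(used)
    c = (Q.T @ t) / P - Q.mean(axis=0) * t.mean()
    grid = db.get_spectrum(used[0].spectrum_id).grid
    return AssocSpectra(grid=grid, feature_kind=used[0].kind, P=P, covariance=c)


def correlation_spectrum(
    hits: HitSet,
    features: "list[FeatureRecord]",
    db: FoodDB,
    mask: "RegionMask | None" = None,
    method: str = "sum_squares",
) -> "AssocSpectra | None":
    """Per-bin Pearson correlation; NaN where variance vanishes."""
    Q, t, used = _paired_arrays(hits, features, db, mask, method)
    if Q is None:
        return None
    P = len(used)
    grid = db.get_spectrum(used[0].spectrum_id).grid
    r = np.full(grid.n_bins, np.nan)
    if P < 2:
        warnings.warn("correlation spectrum needs at least 2 feature records")
        return AssocSpectra(
            grid=grid, feature_kind=used[0].kind, P=P, correlation=r
        )
    qc = Q - Q.mean(axis=0)
    tc = t - t.mean()
    ss_t = float(np.dot(tc, tc))
    ss_q = np.einsum("ij,ij->j", qc, qc)
    if ss_t > 0:
        defined = ss_q > 0
        r[defined] = (qc.T @ tc)[defined] / np.sqrt(ss_q[defined] * ss_t)
        r = np.clip(r, -1.0, 1.0)
    return AssocSpectra(grid=grid, feature_kind=used[0].kind, P=P, correlation=r)


def association_spectra(
    hits: HitSet,
    features: "list[FeatureRecord]",
    db: FoodDB,
    mask: "RegionMask | None" = None,
    method: str = "sum_squares",
) -> "AssocSpectra | None":
    """Covariance and correlation spectra in one pass over the pairs."""
    cov = covariance_spectrum(hits, features, db, mask=mask, method=method)
    if cov is None:
        return None
    corr = correlation_spectrum(hits, features, db, mask=mask, method=method)
    cov.correlation = corr.correlation
    return cov


def estimate_score(
    hits: HitSet, features: "list[FeatureRecord]"
) -> "ScoreEstimate | None":
    """Similarity-weighted average score for the query.

    Weights are w_j = 1/(D_j + Dbar + 1) per feature record; the result
    is a convex combination of the scores, hence inside [min, max].
    Returns None when no hit carries a feature record.
    """
    sim = {h.spectrum_id: h.similarity for h in hits.hits}
    used = [f for f in sorted(features, key=lambda f: f.id) if f.spectrum_id in sim]
    if not used:
        return None
    t = np.array([f.value for f in used])
    d = np.array([sim[f.spectrum_id] for f in used])
    d_bar = d.mean()
    w = 1.0 / (d + d_bar + 1.0)
    weighted = float(np.dot(w, t) / w.sum())
    complete = d == 0.0
    p_prime = int(complete.sum())
    return ScoreEstimate(
        weighted_average=weighted,
        hit_min=float(t.min()),
        hit_max=float(t.max()),
        P=len(used),
        P_prime=p_prime,
        complete_match_average=float(t[complete].mean()) if p_prime else None,
    )
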