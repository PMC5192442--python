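"""PCA summary of a spectrum partition (score/loading plots).

PCA is run on the preprocessed (noise-filtered, normalized, unmasked)
spectra, mean-centered and unscaled, matching the similarity engine's
view of the data.  Component signs are fixed so that each loading's
largest-magnitude element is positive; PCA otherwise leaves signs
arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .database import FoodDB

__all__ = ["PCAResult", "pca", "group_separation_test"]


@dataclass
class PCAResult:
    scores: np.ndarray                  # (n_spectra, k)
    loadings: np.ndarray                # (M, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                    # (M,) bin means used for centering
    spectrum_ids: list[int]
    tags: list[list[str]]


def pca(db: FoodDB, solvent, k: int = 2, method: str = "sum_squares") -> PCAResult:
    """Mean-centered, unscaled PCA of one solvent partition.

    Requires at least k+1 spectra.  Deterministic: full SVD solver plus
    the fixed sign convention.
    """
    ids, X = db.preprocessed_matrix(solvent, mask=None, method=method)
    if len(ids) < k + 1:
        raise ValueError(f"need at least {k + 1} spectra for k={k}, have {len(ids)}")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        mean=model.mean_.copy(),
        spectrum_ids=list(ids),
        tags=[db.tags_of(i) for i in ids],
    )


def group_separation_test(result: PCAResult, tag: str) -> float:
    """Welch two-sample t-test on PC1 scores, tag-bearing vs the rest.

    Returns the p-value; NaN (with a warning) when either group has
    fewer than two members, since the test is then undefined.
    """
    in_group = np.array([tag in t for t in result.tags])
    g1 = result.scores[in_group, 0]
    g2 = result.scores[~in_group, 0]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"tag {tag!r} must split the spectra into two non-empty groups")
    if len(g1) < 2 or len(g2) < 2:
        warnings.warn("single-member group; separation test skipped")
        return float("nan")
    return float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
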