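"""Covariance/correlation spectra and the weighted score estimate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodspec import (
    BinnedSpectrum,
    FeatureKind,
    FoodDB,
    Hit,
    HitSet,
    association_spectra,
    correlation_spectrum,
    covariance_spectrum,
    estimate_score,
    grid_for,
    search,
)
from foodspec.database import FeatureRecord


def single_bin_db(values, bin_index=100):
    """Spectra whose preprocessed intensity at one bin is exactly `value`.

    A spectrum with a single nonzero bin v normalizes to 1/v there, so
    storing 1/value yields a preprocessed intensity of exactly value.
    """
    grid = grid_for("D2O")
    db = FoodDB()
    ids = []
    for k, value in enumerate(values):
        v = np.zeros(grid.n_bins)
        v[bin_index] = 1.0 / value
        rec = db.add_spectrum(BinnedSpectrum(grid=grid, intensities=v, name=f"s{k}"))
        ids.append(rec.id)
    return db, ids


def hitset_for(ids, sims=None):
    sims = sims if sims is not None else [0.01] * len(ids)
    return HitSet(
        query_name="q", threshold=1.0,
        hits=[Hit(i, s) for i, s in sorted(zip(ids, sims), key=lambda p: p[1])],
    )


def feature_records(ids, values, kind=FeatureKind.TASTING):
    return [
        FeatureRecord(j + 1, sid, kind, float(v))
        for j, (sid, v) in enumerate(zip(ids, values))
    ]


def brute_force_covariance(Q, t):
    """Mean-centered two-pass population covariance, one bin at a time."""
    P, M = Q.shape
    qbar = [sum(Q[j, i] for j in range(P)) / P for i in range(M)]
    tbar = sum(t) / len(t)
    return np.array([
        sum((Q[j, i] - qbar[i]) * (t[j] - tbar) for j in range(P)) / P
        for i in range(M)
    ])


def brute_force_pearson(q, t):
    n = len(q)
    qb, tb = sum(q) / n, sum(t) / n
    num = sum((qi - qb) * (ti - tb) for qi, ti in zip(q, t))
    den = (sum((qi - qb) ** 2 for qi in q) * sum((ti - tb) ** 2 for ti in t)) ** 0.5
    return num / den if den > 0 else float("nan")


class TestCovariance:
    def test_two_observation_hand_example(self):
        # intensities (0.1, 0.3), tastings (1, 5):
        # c = (0.1*1 + 0.3*5)/2 - 0.2*3 = 0.2
        db, ids = single_bin_db([0.1, 0.3])
        hits = hitset_for(ids)
        feats = feature_records(ids, [1, 5])
        out = covariance_spectrum(hits, feats, db)
        assert out.covariance[100] == pytest.approx(0.2, abs=1e-12)
        assert out.P == 2
        db.close()

    def test_single_observation_is_all_zero(self):
        db, ids = single_bin_db([0.2])
        out = covariance_spectrum(hitset_for(ids), feature_records(ids, [4]), db)
        np.testing.assert_array_equal(out.covariance, 0.0)
        db.close()

    def test_constant_feature_is_all_zero(self):
        db, ids = single_bin_db([0.1, 0.2, 0.4])
        out = covariance_spectrum(
            hitset_for(ids), feature_records(ids, [3, 3, 3]), db
        )
        np.testing.assert_allclose(out.covariance, 0.0, atol=1e-15)
        db.close()

    def test_no_features_returns_none(self):
        db, ids = single_bin_db([0.1, 0.2])
        assert covariance_spectrum(hitset_for(ids), [], db) is None
        db.close()

    def test_spectrum_with_k_features_contributes_k_pairs(self):
        db, ids = single_bin_db([0.1, 0.3])
        feats = feature_records([ids[0], ids[0], ids[1]], [1, 2, 5])
        out = covariance_spectrum(hitset_for(ids), feats, db)
        # oracle over the three (q, t) pairs
        q = np.array([0.1, 0.1, 0.3])
        t = np.array([1.0, 2.0, 5.0])
        expected = q @ t / 3 - q.mean() * t.mean()
        assert out.P == 3
        assert out.covariance[100] == pytest.approx(expected, abs=1e-14)
        db.close()

    def test_matches_two_pass_oracle_on_synthetic_hits(self, small_db, small_dataset):
        hits = search(small_db, small_dataset.spectra[0], 1.0)
        feats = small_db.features_of(hits.spectrum_ids, "tasting")
        out = covariance_spectrum(hits, feats, small_db)
        from foodspec.assoc_stats import _paired_arrays

        Q, t, _ = _paired_arrays(hits, feats, small_db, None, "sum_squares")
        np.testing.assert_allclose(
            out.covariance, brute_force_covariance(Q, t), atol=1e-12
        )


class TestCorrelation:
    def test_proportional_feature_gives_r_one(self):
        db, ids = single_bin_db([0.1, 0.2, 0.4, 0.5])
        feats = feature_records(ids, [1, 2, 4, 5])
        out = correlation_spectrum(hitset_for(ids), feats, db)
        assert out.correlation[100] == pytest.approx(1.0, abs=1e-12)
        db.close()

    def test_zero_variance_bin_is_undefined_not_zero(self):
        grid = grid_for("D2O")
        db = FoodDB()
        ids = []
        for k, extra in enumerate([0.5, 1.0, 2.0]):
            v = np.zeros(grid.n_bins)
            v[100] = 1.0     # identical across spectra after normalization?
            v[200] = extra
            rec = db.add_spectrum(BinnedSpectrum(grid=grid, intensities=v, name=f"z{k}"))
            ids.append(rec.id)
        feats = feature_records(ids, [1, 3, 5])
        out = correlation_spectrum(hitset_for(ids), feats, db)
        # a bin that is zero in every spectrum has no variance
        assert np.isnan(out.correlation[0])
        db.close()

    def test_fewer_than_two_records_all_undefined_with_warning(self):
        db, ids = single_bin_db([0.1])
        with pytest.warns(UserWarning):
            out = correlation_spectrum(hitset_for(ids), feature_records(ids, [4]), db)
        assert np.isnan(out.correlation).all()
        db.close()

    def test_matches_independent_oracle(self, small_db, small_dataset):
        hits = search(small_db, small_dataset.spectra[1], 1.0)
        feats = small_db.features_of(hits.spectrum_ids, "tasting")
        out = correlation_spectrum(hits, feats, small_db)
        from foodspec.assoc_stats import _paired_arrays

        Q, t, _ = _paired_arrays(hits, feats, small_db, None, "sum_squares")
        for i in range(0, Q.shape[1], 37):
            expected = brute_force_pearson(list(Q[:, i]), list(t))
            if np.isnan(expected):
                assert np.isnan(out.correlation[i])
            else:
                assert out.correlation[i] == pytest.approx(expected, abs=1e-12)

    def test_defined_entries_bounded_and_sign_consistent(self, small_db, small_dataset):
        hits = search(small_db, small_dataset.spectra[4], 1.0)
        feats = small_db.features_of(hits.spectrum_ids, "tasting")
        out = association_spectra(hits, feats, small_db)
        r = out.correlation
        defined = ~np.isnan(r)
        assert np.all(np.abs(r[defined]) <= 1.0)
        both = defined & (np.abs(out.covariance) > 1e-15) & (np.abs(r) > 1e-12)
        assert np.all(np.sign(r[both]) == np.sign(out.covariance[both]))


class TestEstimateScore:
    def test_hand_example_with_complete_match(self):
        # t = (2, 4), D = (0.0, 0.1): Dbar = 0.05, w = (1/1.05, 1/1.15)
        # A = (2/1.05 + 4/1.15)/(1/1.05 + 1/1.15) = 65/22
        db, ids = single_bin_db([0.1, 0.2])
        hits = hitset_for(ids, sims=[0.0, 0.1])
        feats = feature_records(ids, [2, 4])
        est = estimate_score(hits, feats)
        assert est.weighted_average == pytest.approx(65 / 22, abs=1e-12)
        assert est.P == 2 and est.P_prime == 1
        assert est.complete_match_average == pytest.approx(2.0, abs=0)
        assert (est.hit_min, est.hit_max) == (2.0, 4.0)
        db.close()

    def test_uniform_similarity_reduces_to_mean(self):
        db, ids = single_bin_db([0.1, 0.2, 0.3])
        hits = hitset_for(ids, sims=[0.05, 0.05, 0.05])
        est = estimate_score(hits, feature_records(ids, [1, 3, 5]))
        assert est.weighted_average == pytest.approx(3.0, rel=1e-12)
        assert est.P_prime == 0 and est.complete_match_average is None
        db.close()

    def test_single_complete_match(self):
        db, ids = single_bin_db([0.5])
        est = estimate_score(hitset_for(ids, sims=[0.0]), feature_records(ids, [4]))
        assert est.weighted_average == 4.0
        assert est.complete_match_average == 4.0
        db.close()

    def test_no_features_returns_none(self):
        db, ids = single_bin_db([0.5])
        assert estimate_score(hitset_for(ids), []) is None
        db.close()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        t=st.lists(st.integers(1, 5), min_size=2, max_size=12),
        seed=st.integers(0, 2**16),
        shift=st.floats(-3, 3),
    )
    def test_convexity_order_and_shift_invariance(self, t, seed, shift):
        rng = np.random.default_rng(seed)
        ids = list(range(1, len(t) + 1))
        sims = rng.uniform(0, 0.3, len(t))
        hits = hitset_for(ids, sims=list(sims))
        feats = feature_records(ids, t)
        est = estimate_score(hits, feats)
        assert est.hit_min - 1e-12 <= est.weighted_average <= est.hit_max + 1e-12
        # invariant to feature ordering
        perm = list(rng.permutation(len(t)))
        shuffled = [
            FeatureRecord(j + 1, feats[p].spectrum_id, feats[p].kind, feats[p].value)
            for j, p in enumerate(perm)
        ]
        est2 = estimate_score(hits, shuffled)
        assert est2.weighted_average == pytest.approx(est.weighted_average, rel=1e-12)
        # adding a constant shifts the weighted average by that constant
        shifted = [
            FeatureRecord(f.id, f.spectrum_id, f.kind, f.value + shift) for f in feats
        ]
        est3 = estimate_score(hits, shifted)
        assert est3.weighted_average == pytest.approx(
            est.weighted_average + shift, abs=1e-9
        )


class TestPlantedAssociationRecovery:
    def test_lactate_covariance_positive_and_argmax(self, small_db, small_dataset):
        """The planted positive lactate-tasting slope appears as the
        spectrum-wide covariance maximum at the planted bin."""
        hits = search(small_db, small_dataset.spectra[0], 1.0)
        fish_ids = small_db.ids_with_tag("fish")
        feats = small_db.features_of(fish_ids, "tasting")
        out = covariance_spectrum(hits, feats, small_db)
        planted = small_dataset.planted_bins[FeatureKind.TASTING]
        assert out.covariance[planted] > 0
        assert int(np.argmax(out.covariance)) == planted

    def test_constant_shift_leaves_correlation_unchanged(self, small_db, small_dataset):
        hits = search(small_db, small_dataset.spectra[0], 1.0)
        feats = small_db.features_of(hits.spectrum_ids, "tasting")
        shifted = [
            FeatureRecord(f.id, f.spectrum_id, f.kind, f.value + 2.0) for f in feats
        ]
        base = correlation_spectrum(hits, feats, small_db).correlation
        moved = correlation_spectrum(hits, shifted, small_db).correlation
        np.testing.assert_allclose(moved, base, atol=1e-10, equal_nan=True)
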