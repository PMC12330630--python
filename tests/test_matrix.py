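"""Correlation suite: encodings, all-pairs matrices, scaling, filtering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from icitau import (OmicsMatrix, apply_missing_encoding, correlate_all,
                    filter_by_presence, scale_by_dataset_taumax)

from conftest import NAN


def make_matrix(vals, groups=None):
    vals = np.asarray(vals, dtype=float)
    sids = [f"s{j}" for j in range(vals.shape[1])]
    return OmicsMatrix(vals, [f"f{i}" for i in range(vals.shape[0])], sids,
                       groups=groups)


class TestOmicsMatrix:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OmicsMatrix(np.ones((2, 2)), ["f", "f"], ["a", "b"])

    def test_zeros_to_missing_records_provenance(self):
        m = make_matrix([[0.0, 1], [2, 3]]).zeros_to_missing()
        assert np.isnan(m.values[0, 0])
        assert m.mask.sum() == 1
        assert any("zeros_to_missing" in p for p in m.provenance)


class TestMissingEncoding:
    def test_zero_becomes_missing_for_rank_methods(self):
        m = make_matrix([[0.0, 1], [2, 3]])
        for method in ("IK", "IKC", "Kt", "PN0"):
            enc = apply_missing_encoding(m, method)
            assert np.isnan(enc.values[0, 0])

    def test_pb_keeps_zeros_and_zero_fills_missing(self):
        enc = apply_missing_encoding(make_matrix([[0.0, NAN], [2, 3]]), "PB")
        assert enc.values[0, 0] == 0.0 and enc.values[0, 1] == 0.0

    def test_pl1_log1p_maps_zero_to_zero(self):
        enc = apply_missing_encoding(make_matrix([[0.0, 1], [2, 3]]), "PL1")
        assert enc.values[0, 0] == 0.0
        assert enc.values[0, 1] == pytest.approx(np.log(2))

    def test_pl_zero_becomes_missing(self):
        enc = apply_missing_encoding(make_matrix([[0.0, 1], [2, 3]]), "PL")
        assert np.isnan(enc.values[0, 0])

    def test_negative_values_under_log_named(self):
        with pytest.raises(ValueError, match="negative"):
            apply_missing_encoding(make_matrix([[-1.0, 1], [2, 3]]), "PL")


class TestCorrelateAll:
    def test_identical_samples_all_ones(self):
        m = make_matrix(np.tile([[1.0], [2], [3], [4]], (1, 3)))
        tau = correlate_all(m, "IK").tau
        assert np.allclose(tau.to_numpy(), 1.0)

    def test_worked_pair_through_matrix(self, four_feature_matrix):
        mats = correlate_all(four_feature_matrix, "IK")
        assert mats.tau.loc["a", "b"] == pytest.approx(4 / 6, abs=1e-12)
        ikc = correlate_all(four_feature_matrix, "IKC")
        assert ikc.tau.loc["a", "b"] == pytest.approx(4 / 6 * 0.5, abs=1e-12)

    def test_ikc_is_ik_times_completeness(self, grouped_matrix):
        ik = correlate_all(grouped_matrix, "IK")
        ikc = correlate_all(grouped_matrix, "IKC")
        expected = ik.tau.to_numpy() * ik.completeness.to_numpy()
        assert np.allclose(ikc.tau.to_numpy(), expected, atol=1e-12)

    def test_parallel_determinism(self, grouped_matrix):
        results = [correlate_all(grouped_matrix, "IK", cores=c).tau.to_numpy()
                   for c in (1, 2, 8)]
        assert np.array_equal(results[0], results[1])
        assert np.array_equal(results[0], results[2])

    def test_ik_without_missing_equals_classic_taub(self, rng):
        vals = rng.lognormal(1, 0.5, (30, 5))
        mats = correlate_all(make_matrix(vals), "IK")
        for i in range(5):
            for j in range(i + 1, 5):
                ref = kendalltau(vals[:, i], vals[:, j]).statistic
                assert mats.tau.iloc[i, j] == pytest.approx(ref, abs=1e-12)

    def test_pb_equals_pn0_without_zeros(self, rng):
        vals = rng.lognormal(1, 0.5, (20, 4))
        pb = correlate_all(make_matrix(vals), "PB").tau
        pn0 = correlate_all(make_matrix(vals), "PN0").tau
        assert np.allclose(pb.to_numpy(), pn0.to_numpy(), atol=1e-12)

    def test_feature_axis_equals_transposed_samples(self, rng):
        vals = rng.lognormal(1, 0.5, (6, 8))
        by_features = correlate_all(make_matrix(vals), "IK", axis="features")
        transposed = OmicsMatrix(vals.T, [f"s{j}" for j in range(8)],
                                 [f"f{i}" for i in range(6)])
        by_samples = correlate_all(transposed, "IK", axis="samples")
        assert np.allclose(by_features.tau.to_numpy(),
                           by_samples.tau.to_numpy(), atol=1e-12)

    def test_undefined_cell_becomes_nan_with_warning(self):
        vals = np.array([[NAN, 1.0, 1], [NAN, 2, 2], [NAN, 3, 4.0]])
        with pytest.warns(UserWarning, match="undefined"):
            mats = correlate_all(make_matrix(vals), "IK")
        assert np.isnan(mats.tau.loc["s0", "s1"])
        assert mats.tau.loc["s1", "s2"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, grouped_matrix):
        mats = correlate_all(grouped_matrix, "IK")
        a = mats.tau.to_numpy()
        assert np.allclose(a, a.T, equal_nan=True)
        assert np.allclose(np.diag(a), 1.0)


class TestTauMaxScaling:
    def test_identity_when_taumax_is_one(self, rng):
        vals = rng.lognormal(1, 0.5, (30, 4))  # no ties, no missing
        mats = correlate_all(make_matrix(vals), "IK")
        scaled = scale_by_dataset_taumax(mats)
        assert np.allclose(scaled.tau.to_numpy(), mats.tau.to_numpy())

    def test_single_dataset_wide_factor(self, grouped_matrix):
        mats = correlate_all(grouped_matrix, "IK")
        scaled = scale_by_dataset_taumax(mats)
        tm = mats.tau_max.to_numpy().copy()
        np.fill_diagonal(tm, np.nan)
        factor = np.nanmax(tm)
        iu = np.triu_indices(mats.tau.shape[0], 1)
        assert np.allclose(scaled.tau.to_numpy()[iu],
                           mats.tau.to_numpy()[iu] / factor, equal_nan=True)
        assert np.allclose(np.diag(scaled.tau.to_numpy()), 1.0)
        # positive scalar preserves sign and ordering
        assert np.array_equal(np.argsort(mats.tau.to_numpy()[iu]),
                              np.argsort(scaled.tau.to_numpy()[iu]))


class TestPresenceFilter:
    def test_fraction_zero_keeps_everything(self, grouped_matrix):
        out = filter_by_presence(grouped_matrix, 0.0)
        assert out.feature_ids == grouped_matrix.feature_ids

    def test_threshold_arithmetic(self):
        vals = np.full((2, 12), np.nan)
        vals[0, :3] = 1.0   # present in 3 of 12
        vals[1, :] = 1.0
        m = make_matrix(vals)
        assert "f0" in filter_by_presence(m, 0.25).feature_ids
        assert "f0" not in filter_by_presence(m, 0.5).feature_ids

    def test_filtering_everything_raises(self):
        m = make_matrix(np.full((2, 4), np.nan))
        with pytest.raises(ValueError, match="presence"):
            filter_by_presence(m, 0.9)
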