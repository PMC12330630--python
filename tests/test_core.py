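"""Pairwise ICI-Kt: extended pair rules, fast path, tau-max, completeness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kendalltau

from icitau import (DegenerateInputError, UndefinedCorrelationError,
                    completeness, count_pairs_bruteforce, ici_kt, tau_max)
from icitau.core import tau_from_counts

from conftest import NAN, random_pair_with_missing


class TestBruteForceRules:
    def test_identity_ordering_all_concordant(self):
        c = count_pairs_bruteforce([1, 2, 3], [1, 2, 3])
        assert (c.n_concordant, c.n_discordant) == (3, 0)

    def test_disjoint_missingness_creates_discordance(self):
        # pair (0,1): x missing-then-present vs y present-then-missing
        c = count_pairs_bruteforce([NAN, 2, 3, 4], [5, NAN, 7, 8])
        assert c.n_tot == 6
        assert (c.n_concordant, c.n_discordant) == (5, 1)
        assert (c.n_xtie, c.n_ytie, c.n_commontie) == (0, 0, 0)

    def test_co_missing_in_one_vector_is_a_tie(self):
        c = count_pairs_bruteforce([NAN, NAN, 3, 4], [NAN, 6, 7, 8])
        assert (c.n_concordant, c.n_discordant) == (5, 0)
        assert (c.n_xtie, c.n_ytie, c.n_commontie) == (1, 0, 0)

    def test_local_drops_co_missing_before_enumeration(self):
        c = count_pairs_bruteforce([NAN, NAN, 3, 4], [NAN, 6, 7, 8],
                                   perspective="local")
        assert c.n_tot == 3
        assert (c.n_concordant, c.n_discordant) == (3, 0)

    def test_all_missing_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            count_pairs_bruteforce([NAN, NAN, NAN], [1, 2, 3])

    def test_pair_count_partition_invariant(self, rng):
        for _ in range(50):
            x, y = random_pair_with_missing(rng)
            try:
                c = count_pairs_bruteforce(x, y)
            except DegenerateInputError:
                continue
            tied_either = c.n_xtie + c.n_ytie - c.n_commontie
            assert c.n_concordant + c.n_discordant + tied_either == c.n_tot


class TestFastPath:
    def test_worked_examples(self):
        r = ici_kt([NAN, 2, 3, 4], [5, NAN, 7, 8])
        assert r.tau == pytest.approx(4 / 6, abs=1e-12)
        assert r.tau_max == pytest.approx(1.0, abs=1e-12)
        assert r.completeness == pytest.approx(0.5, abs=1e-12)

        r2 = ici_kt([NAN, NAN, 3, 4], [NAN, 6, 7, 8])
        assert r2.tau == pytest.approx(5 / math.sqrt(30), abs=1e-12)

        r2l = ici_kt([NAN, NAN, 3, 4], [NAN, 6, 7, 8], perspective="local")
        assert r2l.tau == pytest.approx(1.0, abs=1e-12)

    def test_oracle_equivalence_random_pairs(self, rng):
        """Mergesort census must match the brute-force rule enumeration."""
        checked = 0
        for _ in range(400):
            x, y = random_pair_with_missing(rng)
            for perspective in ("global", "local"):
                try:
                    c = count_pairs_bruteforce(x, y, perspective)
                except DegenerateInputError:
                    continue
                try:
                    tau_ref, tmax_ref = tau_from_counts(c)
                except UndefinedCorrelationError:
                    with pytest.raises(UndefinedCorrelationError):
                        ici_kt(x, y, perspective)
                    continue
                r = ici_kt(x, y, perspective)
                assert r.tau == pytest.approx(tau_ref, abs=1e-12)
                assert r.tau_max == pytest.approx(tmax_ref, abs=1e-12)
                assert r.counts == c
                checked += 1
        assert checked > 300

    def test_matches_classic_taub_after_sentinel_imputation(self, rng):
        """Global ICI-Kt equals tau-b on sentinel-imputed vectors, for any
        strictly smaller sentinel."""
        for _ in range(50):
            x, y = random_pair_with_missing(rng, n=30)
            if np.isnan(x).all() or np.isnan(y).all():
                continue
            finite_min = np.nanmin(np.concatenate([x, y]))
            for sentinel in (finite_min - 1.0, finite_min - 123.456):
                xi = np.where(np.isnan(x), sentinel, x)
                yi = np.where(np.isnan(y), sentinel, y)
                ref = kendalltau(xi, yi)
                try:
                    r = ici_kt(x, y, p_value=True)
                except UndefinedCorrelationError:
                    assert np.isnan(ref.statistic)
                    continue
                assert r.tau == pytest.approx(ref.statistic, abs=1e-12)
                assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_local_equals_global_without_co_missing(self, rng):
        for _ in range(30):
            x, y = random_pair_with_missing(rng, n=25)
            comiss = np.isnan(x) & np.isnan(y)
            x, y = x[~comiss], y[~comiss]
            if x.size < 2 or np.isnan(x).all() or np.isnan(y).all():
                continue
            try:
                rl = ici_kt(x, y, "local")
                rg = ici_kt(x, y, "global")
            except UndefinedCorrelationError:
                continue
            assert rl.tau == pytest.approx(rg.tau, abs=1e-12)
            assert rl.tau_max == pytest.approx(rg.tau_max, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.one_of(st.none(), st.integers(0, 6)), min_size=4,
                    max_size=25),
           st.lists(st.one_of(st.none(), st.integers(0, 6)), min_size=4,
                    max_size=25),
           st.randoms(use_true_random=False))
    def test_symmetry_and_permutation_invariance(self, xs, ys, rand):
        n = min(len(xs), len(ys))
        x = np.array([np.nan if v is None else float(v) for v in xs[:n]])
        y = np.array([np.nan if v is None else float(v) for v in ys[:n]])
        try:
            r_xy = ici_kt(x, y)
        except (DegenerateInputError, UndefinedCorrelationError):
            return
        try:
            r_yx = ici_kt(y, x)
        except UndefinedCorrelationError:
            return
        assert r_xy.tau == pytest.approx(r_yx.tau, abs=1e-12)
        assert r_xy.completeness == r_yx.completeness
        perm = list(range(n))
        rand.shuffle(perm)
        r_perm = ici_kt(x[perm], y[perm])
        assert r_perm.tau == pytest.approx(r_xy.tau, abs=1e-12)
        assert r_perm.tau_max == pytest.approx(r_xy.tau_max, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(100):
            x, y = random_pair_with_missing(rng)
            try:
                r = ici_kt(x, y)
            except (DegenerateInputError, UndefinedCorrelationError):
                continue
            assert -1 - 1e-12 <= r.tau <= 1 + 1e-12
            assert r.tau <= r.tau_max + 1e-12
            assert 0 < r.tau_max <= 1 + 1e-12
            assert 0 <= r.completeness <= 1

    def test_sorted_and_reversed_extremes(self):
        x = np.arange(10.0)
        assert ici_kt(x, x).tau == 1.0
        assert ici_kt(x, x[::-1]).tau == -1.0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            ici_kt([1.0], [2.0])
        with pytest.raises(DegenerateInputError):
            ici_kt([NAN, NAN, 1.0], [NAN, NAN, 2.0], perspective="local")
        with pytest.raises(UndefinedCorrelationError) as err:
            ici_kt([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])
        assert err.value.counts is not None
        assert err.value.counts.n_xtie == 3


class TestTauMax:
    def test_no_ties_gives_one(self):
        assert tau_max([1, 2, 3, 4], [4, 2, 1, 3]) == pytest.approx(1.0)

    def test_disjoint_single_missing_gives_one(self):
        assert tau_max([NAN, 2, 3, 4], [5, 6, NAN, 8]) == pytest.approx(1.0)

    def test_common_missingness_cancels(self):
        x = [NAN, NAN, 3, 4, 5.0]
        y = [NAN, NAN, 7, 8, 9.0]
        assert tau_max(x, y) == pytest.approx((10 - 1 - 1 + 1) / 9)
        assert tau_max(x, y) == pytest.approx(1.0)


class TestCompleteness:
    @pytest.mark.parametrize("x, y, n_feat, expected", [
        ([1, 2, 3, 4.0], [5, 6, 7, 8.0], None, 1.0),
        ([NAN, 2, 3, 4], [5, NAN, 7, 8], 4, 0.5),
        ([NAN, NAN, 3, 4], [NAN, 6, 7, 8], 4, 0.5),  # union, not sum
    ])
    def test_union_fraction(self, x, y, n_feat, expected):
        assert completeness(x, y, n_feat=n_feat) == pytest.approx(expected)

    def test_zero_feature_space_rejected(self):
        with pytest.raises(DegenerateInputError):
            completeness([1.0, 2.0], [3.0, 4.0], n_feat=0)
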