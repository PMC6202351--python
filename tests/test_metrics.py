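"""Colocalization metric unit and property tests.

Derived expectations are frozen from independent oracles: brute-force set
counting for TOS overlap terms, rank-then-Pearson for SRCC, hand-computed
demeaned sign products for ICQ.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcoloc.metrics import (
    CellPixels,
    ThresholdSpec,
    costes_thresholds,
    icq,
    manders,
    pcc,
    select_top_fraction,
    srcc,
    tos,
    tos_terms,
)

from conftest import make_cell


def brute_force_top(values, f_t):
    """Independent top-fraction selection: explicit sort with the tie rule."""
    values = list(values)
    n = len(values)
    n_sel = n if f_t == 1.0 else max(1, int(np.floor(f_t * n + 0.5)))
    order = sorted(range(n), key=lambda i: (-values[i], i))
    return set(order[:n_sel])


def brute_force_tos(ch1, ch2, f1, f2):
    """TOS by explicit set intersection, independent of the library path."""
    n = len(ch1)
    s1, s2 = brute_force_top(ch1, f1), brute_force_top(ch2, f2)
    a_o = len(s1 & s2) / n
    g1, g2 = len(s1) / n, len(s2) / n
    a_e = g1 * g2
    a_max = min(g1, g2)
    a_min = max(0.0, g1 + g2 - 1.0)
    if a_o >= a_e:
        return (a_o - a_e) / (a_max - a_e) if a_max > a_e else np.nan
    return (a_o - a_e) / (a_e - a_min) if a_e > a_min else np.nan


class TestSelectTopFraction:
    def test_picks_highest_values(self):
        assert list(select_top_fraction([10, 30, 20, 40], 0.5)) == [1, 3]

    def test_full_fraction_selects_all(self):
        assert list(select_top_fraction([3, 1, 2], 1.0)) == [0, 1, 2]

    def test_ties_broken_by_pixel_index(self):
        assert list(select_top_fraction([5, 5, 5, 5], 0.5)) == [0, 1]

    def test_at_least_one_pixel(self):
        assert list(select_top_fraction([4, 9, 1], 0.01)) == [1]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_rejects_out_of_range_fraction(self, bad):
        with pytest.raises(ValueError):
            select_top_fraction([1, 2], bad)

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=40),
           st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_selection(self, values, f_t):
        got = set(select_top_fraction(values, f_t))
        assert got == brute_force_top(values, f_t)


class TestTos:
    def test_identical_channels_give_plus_one(self):
        cell = make_cell(np.arange(100), np.arange(100))
        spec = ThresholdSpec(0.1, 0.1)
        assert tos(cell, spec, "linear") == 1.0
        assert tos(cell, spec, "log") == 1.0

    def test_disjoint_top_halves_give_minus_one(self):
        a = np.concatenate([np.full(50, 10.0), np.full(50, 1.0)])
        b = np.concatenate([np.full(50, 1.0), np.full(50, 10.0)])
        cell = make_cell(a, b)
        assert tos(cell, ThresholdSpec(0.5, 0.5), "linear") == -1.0
        assert tos(cell, ThresholdSpec(0.5, 0.5), "log") == -1.0

    def test_partial_overlap_value(self):
        # N=100, f=(0.2, 0.3), overlap 10 px: (0.10-0.06)/(0.20-0.06)
        a = np.zeros(100)
        b = np.zeros(100)
        a[:20] = 100 - np.arange(20)
        b[10:40] = 100 - np.arange(30)
        cell = make_cell(a, b)
        got = tos(cell, ThresholdSpec(0.2, 0.3))
        assert got == pytest.approx((0.10 - 0.06) / (0.20 - 0.06))
        assert got == pytest.approx(brute_force_tos(a, b, 0.2, 0.3))

    def test_full_threshold_is_nan(self):
        cell = make_cell(np.arange(10), np.arange(10))
        assert np.isnan(tos(cell, ThresholdSpec(1.0, 0.5)))
        assert np.isnan(tos(cell, ThresholdSpec(1.0, 1.0), "log"))

    def test_terms_bounds_invariant(self, rng):
        for _ in range(50):
            cell = make_cell(rng.integers(0, 30, 60), rng.integers(0, 30, 60))
            f1, f2 = rng.choice([0.1, 0.25, 0.5, 0.9], 2)
            t = tos_terms(cell, ThresholdSpec(float(f1), float(f2)))
            assert t.a_min - 1e-12 <= t.a_o <= t.a_max + 1e-12
            assert t.a_min - 1e-12 <= t.a_e <= t.a_max + 1e-12

    def test_formula_equals_brute_force_on_random_cells(self, rng):
        grid = np.arange(0.1, 1.001, 0.1)
        for _ in range(30):
            vals1 = rng.integers(0, 20, 100).astype(float)
            vals2 = rng.integers(0, 20, 100).astype(float)
            cell = make_cell(vals1, vals2)
            for f1 in grid:
                for f2 in grid:
                    got = tos(cell, ThresholdSpec(float(f1), float(f2)))
                    want = brute_force_tos(vals1, vals2, float(f1), float(f2))
                    assert (np.isnan(got) and np.isnan(want)) or got == want

    def test_channel_permutation_symmetry(self, rng):
        a, b = rng.integers(0, 50, 80), rng.integers(0, 50, 80)
        s = ThresholdSpec(0.2, 0.2)
        assert tos(make_cell(a, b), s) == tos(make_cell(b, a), s)

    def test_three_channel_extremes(self):
        v = np.arange(60, dtype=float)
        cell = make_cell(v, v, v)
        assert tos(cell, ThresholdSpec(0.1, 0.1, 0.1)) == 1.0
        # disjoint thirds -> A_O = 0, A_min = 0 -> -1
        a = np.zeros(60); a[:20] = 9
        b = np.zeros(60); b[20:40] = 9
        c = np.zeros(60); c[40:] = 9
        third = ThresholdSpec(1 / 3, 1 / 3, 1 / 3)
        assert tos(make_cell(a, b, c), third) == -1.0


class TestCorrelations:
    def test_pcc_perfect_linear(self):
        assert pcc(make_cell([1, 2, 3], [2, 4, 6])) == pytest.approx(1.0)

    def test_pcc_hand_value(self):
        assert pcc(make_cell([1, 2, 3, 4], [1, 3, 2, 4])) == pytest.approx(0.8)

    def test_pcc_constant_is_nan(self):
        assert np.isnan(pcc(make_cell([5, 5, 5], [1, 2, 3])))

    def test_srcc_monotone_transform(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert srcc(make_cell(a, np.exp(a))) == pytest.approx(1.0)
        assert srcc(make_cell(a, a[::-1])) == pytest.approx(-1.0)

    def test_srcc_rank_oracle(self, rng):
        from scipy.stats import rankdata

        a, b = rng.normal(size=30), rng.normal(size=30)
        ra, rb = rankdata(a), rankdata(b)
        want = np.corrcoef(ra, rb)[0, 1]
        assert srcc(make_cell(a, b)) == pytest.approx(want)

    def test_scipy_cross_check(self, rng):
        from scipy import stats

        a = rng.integers(0, 10, 50).astype(float)
        b = rng.integers(0, 10, 50).astype(float)
        assert pcc(make_cell(a, b)) == pytest.approx(stats.pearsonr(a, b)[0])
        assert srcc(make_cell(a, b)) == pytest.approx(stats.spearmanr(a, b)[0])

    def test_threshold_restriction_is_intersection(self):
        a = np.array([10.0, 9, 8, 1, 2, 3])
        b = np.array([10.0, 9, 1, 8, 2, 3])
        # top half: A -> {0,1,2}, B -> {0,1,3}; intersection {0,1}
        spec = ThresholdSpec(0.5, 0.5)
        want = np.corrcoef([10, 9], [10, 9])[0, 1]
        assert pcc(make_cell(a, b), spec) == pytest.approx(want)


class TestIcq:
    def test_identical_gives_half(self):
        assert icq(make_cell([1, 2, 3, 4], [1, 2, 3, 4])) == pytest.approx(0.5)

    def test_inverted_gives_minus_half(self):
        a = np.array([1.0, 2, 3, 4])
        assert icq(make_cell(a, 10 - a)) == pytest.approx(-0.5)

    def test_hand_value_zero(self):
        assert icq(make_cell([1, 2, 3, 4], [4, 1, 2, 3])) == pytest.approx(0.0)

    def test_zero_products_excluded(self):
        # demeaned products: (+4, 0, 0) -> only the first pixel is valid
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 9.0, 5.0])
        assert icq(make_cell(a, b)) == pytest.approx(0.5)

    def test_three_channel_bounds(self, rng):
        v = np.arange(40, dtype=float)
        assert icq(make_cell(v, v, v)) == pytest.approx(0.75)
        a, b, c = (rng.normal(size=200) for _ in range(3))
        q = icq(make_cell(a, b, c))
        assert -0.25 - 1e-12 <= q <= 0.75 + 1e-12


class TestManders:
    def test_full_threshold_gives_one(self):
        cell = make_cell([1, 2, 3, 4], [4, 3, 2, 1])
        assert manders(cell, ThresholdSpec(1.0, 1.0)) == (1.0, 1.0)

    def test_direct_sum_value(self):
        # channel-2 top half selects pixels {0, 3}; M1 = (5+4)/10
        a = np.array([5.0, 1.0, 0.0, 4.0])
        b = np.array([9.0, 1.0, 2.0, 8.0])
        m1, m2 = manders(make_cell(a, b), ThresholdSpec(0.5, 0.5))
        assert m1 == pytest.approx(0.9)

    def test_zero_channel_is_nan(self):
        m1, m2 = manders(make_cell([0.0, 0.0], [1.0, 2.0]), ThresholdSpec(0.5, 0.5))
        assert np.isnan(m1)
        assert 0.0 <= m2 <= 1.0

    def test_monotone_in_other_channel_fraction(self, rng):
        a = rng.uniform(1, 10, 100)
        b = rng.uniform(1, 10, 100)
        cell = make_cell(a, b)
        prev = 0.0
        for f2 in [0.1, 0.3, 0.5, 0.8, 1.0]:
            m1 = manders(cell, ThresholdSpec(0.5, f2))[0]
            assert m1 >= prev - 1e-12
            prev = m1

    def test_three_channel_requires_both_others(self):
        a = np.array([1.0, 1, 1, 1])
        b = np.array([9.0, 1, 9, 1])
        c = np.array([9.0, 9, 1, 1])
        # only pixel 0 is in the top half of both B and C
        m = manders(make_cell(a, b, c), ThresholdSpec(0.5, 0.5, 0.5))
        assert m[0] == pytest.approx(0.25)


class TestCostes:
    def test_perfectly_correlated_descends_with_warning(self):
        a = np.arange(1, 101, dtype=float)
        cell = make_cell(a, a)
        with pytest.warns(UserWarning, match="descended"):
            t_a, t_b = costes_thresholds(cell)
        assert t_a == a.min()

    def test_independent_noise_threshold_in_top_decile(self, rng):
        a = rng.uniform(0, 1000, 5000)
        b = rng.uniform(0, 1000, 5000)
        t_a, _ = costes_thresholds(make_cell(a, b))
        assert np.mean(a < t_a) >= 0.9

    def test_scan_oracle_agreement(self, rng):
        """First non-positive below-threshold PCC, recomputed independently."""
        a = rng.uniform(0, 100, 200)
        b = 0.5 * a + rng.uniform(0, 60, 200)
        t_a, t_b = costes_thresholds(make_cell(a, b))
        slope, intercept = np.polyfit(a, b, 1)
        expected = None
        for cand in np.unique(a)[::-1]:
            cb = intercept + slope * cand
            below = (a < cand) & (b < cb)
            if below.sum() < 2:
                continue
            x, y = a[below], b[below]
            if x.std() == 0 or y.std() == 0:
                continue
            if np.corrcoef(x, y)[0, 1] <= 0:
                expected = cand
                break
        assert expected is not None
        assert t_a == pytest.approx(expected)
        assert t_b == pytest.approx(intercept + slope * expected)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            costes_thresholds(make_cell([1, 2, 3], [1, 2, 3]))


@given(
    st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=40),
    st.floats(0.1, 10),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_scale_invariance(values, scale):
    """PCC/SRCC/ICQ/TOS unchanged by positive affine rescale of a channel."""
    rng = np.random.default_rng(7)
    a = np.round(np.asarray(values), 3)  # avoid float-precision collapse
    b = rng.permutation(a) + rng.normal(0, 1, a.size)
    cell1 = make_cell(a, b)
    cell2 = make_cell(a * scale + 3.0, b)
    spec = ThresholdSpec(0.5, 0.5)
    for fn in (pcc, srcc, icq):
        v1, v2 = fn(cell1), fn(cell2)
        assert (np.isnan(v1) and np.isnan(v2)) or v1 == pytest.approx(v2)
    t1, t2 = tos(cell1, spec), tos(cell2, spec)
    assert (np.isnan(t1) and np.isnan(t2)) or t1 == pytest.approx(t2)


def test_metric_ranges_on_random_cells(rng):
    for _ in range(100):
        n = int(rng.integers(4, 60))
        cell = make_cell(rng.integers(0, 15, n), rng.integers(0, 15, n))
        spec = ThresholdSpec(*rng.choice([0.2, 0.5, 0.8], 2).tolist())
        t = tos(cell, spec)
        assert np.isnan(t) or -1.0 - 1e-12 <= t <= 1.0 + 1e-12
        for fn, lo, hi in ((pcc, -1, 1), (srcc, -1, 1), (icq, -0.5, 0.5)):
            v = fn(cell)
            assert np.isnan(v) or lo - 1e-9 <= v <= hi + 1e-9
        for m in manders(cell, spec):
            assert np.isnan(m) or 0.0 <= m <= 1.0 + 1e-12
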