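"""Area-weighted distribution machinery and group tests."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from memthick.stats import (area_weighted_histogram, area_weighted_median,
                            hist2d, mann_whitney_u, per_component_medians,
                            quantile_partition)


class TestHistogram:
    def test_single_value_single_bin(self):
        centers, h = area_weighted_histogram([1.5], [2.0], [0, 1, 2, 3])
        assert h.sum() == 1.0
        assert h[1] == 1.0

    def test_weighted_two_values(self):
        _, h = area_weighted_histogram([1, 3], [1, 3], [0, 2, 4])
        np.testing.assert_allclose(h, [0.25, 0.75])

    def test_heights_normalized(self, rng):
        v = rng.uniform(2, 6, 500)
        w = rng.uniform(0.1, 2.0, 500)
        _, h = area_weighted_histogram(v, w, np.linspace(2, 6, 17))
        assert h.sum() == pytest.approx(1.0, abs=1e-12)

    def test_right_edge_falls_in_lower_bin(self):
        _, h = area_weighted_histogram([2.0], [1.0], [0, 2, 4])
        assert h[0] == 1.0  # 2.0 belongs to (0, 2], not [2, 4)

    def test_empty_after_masking_errors(self):
        with pytest.raises(ValueError):
            area_weighted_histogram([np.nan], [1.0], [0, 1])


class TestWeightedMedian:
    def test_equal_weights_is_lower_median(self):
        assert area_weighted_median([1, 2, 3, 4], np.ones(4)) == 2

    def test_heavy_tail_dominates(self):
        assert area_weighted_median([1, 2, 10], [1, 1, 10]) == 10

    def test_matches_cumulative_sum_oracle(self, rng):
        for _ in range(20):
            v = rng.normal(size=50)
            w = rng.uniform(0.1, 3.0, 50)
            order = np.argsort(v)
            cum = np.cumsum(w[order])
            expected = v[order][np.searchsorted(cum, cum[-1] / 2)]
            assert area_weighted_median(v, w) == expected

    def test_invariant_to_triangle_subdivision(self, rng):
        """Splitting any triangle into equal-area children with the same
        value must not move the median."""
        v = rng.normal(size=30)
        w = rng.uniform(0.5, 2.0, 30)
        v2 = np.r_[v, v[3], v[3]]
        w2 = np.r_[w, w[3] / 3, w[3] / 3]
        w2[3] = w[3] / 3
        assert area_weighted_median(v2, w2) == area_weighted_median(v, w)


class TestPerComponentMedians:
    def test_single_component(self, rng):
        v = rng.normal(3.6, 0.1, 40)
        med, dropped = per_component_medians(np.zeros(40, int), v,
                                             np.ones(40))
        assert set(med) == {0} and not dropped

    def test_disjoint_ranges_give_distinct_medians(self):
        comp = np.r_[np.zeros(20, int), np.ones(20, int)]
        v = np.r_[np.full(20, 3.2), np.full(20, 4.0)]
        med, _ = per_component_medians(comp, v, np.ones(40))
        assert med[0] == 3.2 and med[1] == 4.0

    def test_small_components_dropped_and_reported(self):
        comp = np.r_[np.zeros(20, int), np.ones(5, int)]
        v = np.ones(25)
        med, dropped = per_component_medians(comp, v, np.ones(25))
        assert 0 in med and dropped == [1]


class TestMannWhitney:
    def test_fully_separated_small_groups_exact(self):
        u, p = mann_whitney_u([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert u == 0
        assert p == pytest.approx(2 / comb(10, 5), rel=1e-9)

    def test_identical_groups_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = mann_whitney_u(a, a)
        assert p > 0.9

    def test_symmetric_in_group_order(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(0.5, 1.0, 15)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(b, a)
        assert u1 == u2 and p1 == pytest.approx(p2, rel=1e-12)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        """Brute-force enumeration over all group labelings (no ties)."""
        # overlapping ranges, ties impossible (evens vs odds)
        a = sorted((2 * rng.choice(50, 6, replace=False)).astype(float))
        b = sorted((2 * rng.choice(50, 7, replace=False) + 1).astype(float))
        u_obs, p = mann_whitney_u(a, b)
        pooled = np.array(list(a) + list(b))
        n_a = len(a)

        def u_min(idx_a):
            ranks = pooled.argsort().argsort() + 1
            ra = ranks[list(idx_a)].sum()
            ua = ra - n_a * (n_a + 1) / 2
            return min(ua, n_a * len(b) - ua)

        u_all = [u_min(c) for c in
                 combinations(range(len(pooled)), n_a)]
        expected = np.mean(np.array(u_all) <= u_obs)  # two-sided via min-U
        # two-sided exact p: P(U_min <= observed U_min)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_type_one_error_control_on_null_splits(self, rng):
        """p-values under the null (random splits of one population) are
        roughly uniform: a KS check over 200 resampled splits."""
        from scipy.stats import kstest
        pop = rng.normal(size=40)
        ps = []
        for _ in range(200):
            idx = rng.permutation(40)
            _, p = mann_whitney_u(pop[idx[:20]], pop[idx[20:]])
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestQuantilePartition:
    def test_top_band_contains_extreme_values(self):
        v = np.arange(1.0, 101.0)
        labels, thr = quantile_partition(v)
        top = v[labels == "0.99-1"]
        assert np.all(top >= thr[-2])
        assert 100.0 in top

    def test_constant_values_first_band(self):
        labels, _ = quantile_partition(np.full(50, 2.0))
        assert np.all(labels == "0-0.5")

    def test_band_fractions_for_continuous_data(self, rng):
        v = rng.uniform(size=10_000)
        labels, _ = quantile_partition(v)
        fracs = {name: np.mean(labels == name)
                 for name in ("0-0.5", "0.5-0.9", "0.9-0.95",
                              "0.95-0.99", "0.99-1")}
        for name, target in [("0-0.5", 0.5), ("0.5-0.9", 0.4),
                             ("0.9-0.95", 0.05), ("0.95-0.99", 0.04),
                             ("0.99-1", 0.01)]:
            assert fracs[name] == pytest.approx(target, abs=0.005)


class TestHist2D:
    def test_single_point_unit_mass(self):
        H = hist2d([1.5], [2.5], [3.0], [0, 1, 2], [2, 3])
        assert H.sum() == 1.0 and H[1, 0] == 1.0

    def test_marginals_reproduce_1d_histograms(self, rng):
        x = rng.uniform(1, 5, 300)
        y = rng.uniform(0, 2, 300)
        w = rng.uniform(0.1, 1.0, 300)
        xe = np.linspace(1, 5, 9)
        ye = np.linspace(0, 2, 5)
        H = hist2d(x, y, w, xe, ye)
        _, hx = area_weighted_histogram(x, w, xe)
        _, hy = area_weighted_histogram(y, w, ye)
        np.testing.assert_allclose(H.sum(axis=1), hx, atol=1e-12)
        np.testing.assert_allclose(H.sum(axis=0), hy, atol=1e-12)

    def test_independent_variables_uncorrelated(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 1.5, n)
        r = (np.average(x * y, weights=w)
             - np.average(x, weights=w) * np.average(y, weights=w))
        r /= (np.sqrt(np.average(x**2, weights=w)
                      - np.average(x, weights=w)**2)
              * np.sqrt(np.average(y**2, weights=w)
                        - np.average(y, weights=w)**2))
        assert abs(r) < 0.05
        H = hist2d(x, y, w, np.linspace(-4, 4, 20), np.linspace(-4, 4, 20))
        assert H.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reindexing_invariance(self, rng):
        v = rng.uniform(1, 5, 100)
        w = rng.uniform(0.1, 1.0, 100)
        perm = rng.permutation(100)
        edges = np.linspace(1, 5, 9)
        _, h1 = area_weighted_histogram(v, w, edges)
        _, h2 = area_weighted_histogram(v[perm], w[perm], edges)
        np.testing.assert_allclose(h1, h2, atol=1e-14)
        assert area_weighted_median(v, w) == \
            area_weighted_median(v[perm], w[perm])


class TestWeightedMedianProperties:
    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3, allow_nan=False,
                              allow_infinity=False),
                    min_size=1, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_median_is_attained_and_bounded(self, values, wseed):
        v = np.asarray(values)
        w = np.random.default_rng(wseed).uniform(0.1, 5.0, v.size)
        m = area_weighted_median(v, w)
        assert m in v
        assert v.min() <= m <= v.max()
        # at least half the total weight sits at or below the median
        assert w[v <= m].sum() >= w.sum() / 2 - 1e-9
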