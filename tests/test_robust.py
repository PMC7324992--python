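"""Robust estimator unit tests against brute-force and library oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.covariance import MinCovDet

from rpcaqc import fast_mcd, l1_median, mad, qn, unimcd

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestMad:
    def test_reference_value(self):
        # median |x - 3| of (1..5) is 1
        assert mad(np.array([1, 2, 3, 4, 5.0])) == pytest.approx(1.4826)

    def test_constant_vector_is_zero(self):
        assert mad(np.full(9, 3.7)) == 0.0

    def test_gaussian_consistency(self, rng):
        x = rng.normal(size=200_000)
        assert mad(x) == pytest.approx(1.0, abs=0.01)

    @given(st.lists(finite_floats, min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_definition(self, xs):
        x = np.array(xs)
        med = sorted(xs)[len(xs) // 2] if len(xs) % 2 else \
            (sorted(xs)[len(xs) // 2 - 1] + sorted(xs)[len(xs) // 2]) / 2
        expected = 1.4826 * sorted(abs(v - med) for v in xs)[len(xs) // 2] \
            if len(xs) % 2 else \
            1.4826 * (sorted(abs(v - med) for v in xs)[len(xs) // 2 - 1]
                      + sorted(abs(v - med) for v in xs)[len(xs) // 2]) / 2
        assert mad(x) == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestQn:
    def test_two_points(self):
        # single pairwise difference times consistency and n=2 correction
        assert qn(np.array([3.0, 5.0])) == pytest.approx(2.2219 * 0.399 * 2.0)

    @pytest.mark.parametrize("n", [3, 5, 8, 12, 25, 50])
    def test_brute_force_enumeration(self, n, rng):
        """k-th order statistic of all pairwise distances, enumerated."""
        x = rng.normal(size=n) * 3 + 1
        diffs = sorted(abs(a - b) for a, b in combinations(x, 2))
        h = n // 2 + 1
        k = h * (h - 1) // 2
        from rpcaqc.robust import _qn_correction

        expected = 2.2219 * _qn_correction(n) * diffs[k - 1]
        assert qn(x) == pytest.approx(expected, rel=1e-12)

    def test_gaussian_consistency(self, rng):
        x = rng.normal(size=2000)
        assert qn(x) == pytest.approx(1.0, abs=0.06)

    def test_agrees_with_statsmodels_asymptotically(self, rng):
        from statsmodels.robust.scale import qn_scale

        x = rng.normal(size=1500)
        assert qn(x) == pytest.approx(qn_scale(x), rel=0.02)


class TestUniMcd:
    @pytest.mark.parametrize("n,alpha", [(6, 0.5), (8, 0.75), (10, 0.6), (12, 0.75)])
    def test_exhaustive_subset_oracle(self, n, alpha, rng):
        """The minimal-variance h-subset over ALL C(n,h) subsets equals the
        contiguous-window optimum the implementation scans."""
        x = rng.normal(size=n) * 2 + 5
        h = math.ceil(alpha * n)
        best = min(
            (np.var(sub, ddof=1), np.mean(sub))
            for sub in (np.array(c) for c in combinations(x, h))
        )
        fit = unimcd(x, alpha)
        from rpcaqc.robust import _mcd_consistency

        assert fit.location == pytest.approx(best[1], rel=1e-10)
        assert fit.scale == pytest.approx(
            math.sqrt(best[0] * _mcd_consistency(h / n, 1)), rel=1e-10
        )

    def test_full_sample_is_classical(self, rng):
        x = rng.normal(size=50)
        fit = unimcd(x, alpha=1.0)
        assert fit.location == pytest.approx(x.mean())
        assert fit.scale == pytest.approx(x.std(ddof=1))

    def test_tied_window_gives_zero_scale(self):
        fit = unimcd(np.array([0, 0, 0, 0, 100.0]), alpha=0.75)
        assert fit.location == 0.0
        assert fit.scale == 0.0

    def test_equivariance(self, rng):
        x = rng.normal(size=15)
        f1 = unimcd(x, 0.75)
        f2 = unimcd(3.0 * x + 7.0, 0.75)
        assert f2.location == pytest.approx(3 * f1.location + 7, rel=1e-9)
        assert f2.scale == pytest.approx(3 * f1.scale, rel=1e-9)


class TestL1Median:
    def test_univariate_is_median(self, rng):
        x = rng.normal(size=11).reshape(-1, 1)
        assert l1_median(x)[0] == pytest.approx(np.median(x), abs=1e-6)

    def test_symmetric_point_set(self):
        X = np.array([[1, 0], [-1, 0], [0, 2], [0, -2.0]])
        assert np.allclose(l1_median(X), [0, 0], atol=1e-7)

    def test_coincides_with_data_point_optimum(self):
        # the central point dominates: optimum is the data point itself
        X = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1.0]])
        assert np.allclose(l1_median(X), [0, 0], atol=1e-7)

    @pytest.mark.parametrize("n", [4, 5, 7])
    def test_objective_against_grid_search(self, n, rng):
        X = rng.normal(size=(n, 2))
        m = l1_median(X, tol=1e-10)
        obj = np.linalg.norm(X - m, axis=1).sum()
        # refined grid around the returned point must not beat it meaningfully
        grid = np.linspace(-2, 2, 81)
        cand = np.array([[a, b] for a in grid for b in grid])
        objs = np.linalg.norm(X[None] - cand[:, None], axis=2).sum(axis=1)
        assert obj <= objs.min() + 1e-3


class TestFastMcd:
    def test_1d_reduces_to_unimcd(self, rng):
        x = np.concatenate([rng.normal(size=18), [8.0, 9.0]])
        fit = fast_mcd(x.reshape(-1, 1), alpha=0.75, seed=3)
        uni = unimcd(x, 0.75)
        raw_scale = math.sqrt(fit.raw_scatter[0, 0])
        assert raw_scale == pytest.approx(uni.scale, rel=1e-6)

    @pytest.mark.parametrize("n,k", [(8, 1), (9, 2), (10, 2)])
    def test_exhaustive_h_subset_oracle(self, n, k, rng):
        """Raw MCD determinant equals the minimum over all h-subsets."""
        Y = rng.normal(size=(n, k))
        alpha = 0.75
        h = max(math.ceil(alpha * n), k + 1)
        best = min(
            np.linalg.det(np.cov(Y[list(c)], rowvar=False, ddof=1).reshape(k, k))
            for c in combinations(range(n), h)
        )
        fit = fast_mcd(Y, alpha=alpha, seed=5, n_starts=2000)
        assert fit.raw_determinant == pytest.approx(best, rel=1e-8)

    def test_alpha_one_is_classical(self, rng):
        Y = rng.normal(size=(40, 3))
        fit = fast_mcd(Y, alpha=1.0, seed=0)
        assert np.allclose(fit.center, Y.mean(axis=0))
        assert np.allclose(fit.scatter, np.cov(Y, rowvar=False))

    def test_planted_outliers_excluded_from_support(self, rng):
        clean = rng.normal(size=(20, 2))
        gross = np.array([[10.0, 10.0], [11, -10], [-10, 12]])
        Y = np.vstack([clean, gross])
        fit = fast_mcd(Y, alpha=0.75, seed=7)
        assert not set(range(20, 23)) & set(fit.support.tolist())

    def test_affine_equivariance(self, rng):
        Y = rng.normal(size=(25, 2))
        A = np.array([[2.0, 0.5], [0.0, 1.5]])
        b = np.array([3.0, -1.0])
        f1 = fast_mcd(Y, 0.75, seed=11)
        f2 = fast_mcd(Y @ A.T + b, 0.75, seed=11)
        assert np.allclose(f2.center, f1.center @ A.T + b, atol=1e-6)
        assert np.allclose(f2.scatter, A @ f1.scatter @ A.T, atol=1e-6)

    def test_cross_check_sklearn_raw_subset(self, rng):
        """Independent FAST-MCD (scikit-learn) finds no better h-subset."""
        Y = np.vstack([rng.normal(size=(26, 2)), [[6, 6], [7, -6.0]]])
        ours = fast_mcd(Y, alpha=0.75, seed=2)
        sk = MinCovDet(support_fraction=0.75, random_state=0).fit(Y)
        sk_det = np.linalg.det(
            np.cov(Y[sk.raw_support_], rowvar=False, ddof=1)
        )
        assert ours.raw_determinant <= sk_det * (1 + 1e-6)
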