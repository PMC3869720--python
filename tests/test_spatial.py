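"""Ripley K/L estimators and the isotropic edge correction."""

import numpy as np
import pytest

from forestspat import (
    L_transform, PointPattern, RGrid, Window, isotropic_edge_weight,
    pairwise_distances, ripley_K, ripley_K12, simulate_csr,
)
from forestspat.errors import InsufficientPointsError
from forestspat.spatial import SummaryCurve


class TestPairwiseDistances:
    def test_three_four_five(self, square):
        p = PointPattern(square, [(0, 0), (3, 4)])
        d = pairwise_distances(p)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)

    def test_matches_double_loop(self, square, rng):
        pts = rng.random((100, 2)) * 100
        p = PointPattern(square, pts)
        d = pairwise_distances(p)
        for _ in range(50):
            i, j = rng.integers(0, 100, 2)
            assert d[i, j] == pytest.approx(np.hypot(*(pts[i] - pts[j])))

    def test_duplicate_warns(self, square):
        p = PointPattern(square, [(1, 1), (1, 1), (5, 5)])
        with pytest.warns(UserWarning, match="duplicate"):
            pairwise_distances(p)

    def test_single_point_raises(self, square):
        with pytest.raises(InsufficientPointsError):
            pairwise_distances(PointPattern(square, [(1, 1)]))


class TestEdgeWeight:
    def test_interior_edge_corner(self, square):
        assert isotropic_edge_weight((50, 50), 10, square) == 1.0
        assert isotropic_edge_weight((0, 50), 10, square) == \
            pytest.approx(2.0)
        assert isotropic_edge_weight((0, 0), 10, square) == \
            pytest.approx(4.0)

    def test_weight_one_iff_circle_inside(self, square, rng):
        for _ in range(200):
            x, y = rng.random(2) * 100
            d = rng.random() * 50
            if d <= 0:
                continue
            w = isotropic_edge_weight((x, y), d, square)
            inside = min(x, 100 - x, y, 100 - y) >= d
            if inside:
                assert w == 1.0
            else:
                assert w > 1.0

    def test_matches_numeric_arc_integration(self, square, rng):
        """Analytic arc formula against a fine numeric circle sample."""
        for _ in range(50):
            x, y = rng.random(2) * 100
            d = 1.0 + rng.random() * 48.0
            w = isotropic_edge_weight((x, y), d, square)
            theta = np.linspace(0, 2 * np.pi, 200_001)[:-1]
            px, py = x + d * np.cos(theta), y + d * np.sin(theta)
            frac = ((px >= 0) & (px <= 100) & (py >= 0) & (py <= 100)).mean()
            assert w == pytest.approx(1.0 / frac, rel=1e-3)


class TestRipleyK:
    def test_two_interior_points(self, square):
        p = PointPattern(square, [(45, 50), (50, 50)])
        grid = RGrid(20, 20)
        K = ripley_K(p, grid)
        assert np.all(K.values[grid.r < 5] == 0)
        assert np.all(K.values[grid.r >= 5] == pytest.approx(10_000.0))

    def test_monotone_nondecreasing(self, square, rng):
        p = PointPattern(square, rng.random((80, 2)) * 100)
        K = ripley_K(p, RGrid(25, 128))
        assert np.all(np.diff(K.values) >= -1e-9)
        assert K.values[0] == 0.0

    def test_matches_brute_force(self, square, rng):
        """Direct O(n^2 * n_steps) recomputation with explicit weights."""
        pts = rng.random((50, 2)) * 100
        p = PointPattern(square, pts)
        grid = RGrid(25, 64)
        K = ripley_K(p, grid)
        expected = np.zeros(grid.n_steps + 1)
        for k, r in enumerate(grid.r):
            acc = 0.0
            for i in range(50):
                for j in range(50):
                    if i == j:
                        continue
                    d = np.hypot(*(pts[i] - pts[j]))
                    if d <= r:
                        acc += isotropic_edge_weight(pts[i], d, square)
            expected[k] = square.area / (50 * 49) * acc
        np.testing.assert_allclose(K.values, expected, rtol=1e-10)

    def test_interior_cluster_equals_uncorrected(self, square, rng):
        """Far from edges every weight is 1: plain pair counting."""
        pts = 45 + rng.random((30, 2)) * 10
        p = PointPattern(square, pts)
        grid = RGrid(4, 32)
        K = ripley_K(p, grid)
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        expected = [square.area / (30 * 29) * (d <= r).sum()
                    for r in grid.r]
        np.testing.assert_allclose(K.values, expected, rtol=1e-12)

    def test_r_max_validity_guard(self, square, rng):
        p = PointPattern(square, rng.random((10, 2)) * 100)
        with pytest.raises(ValueError, match="half the shorter"):
            ripley_K(p, RGrid(60, 10))

    def test_insufficient_points(self, square):
        with pytest.raises(InsufficientPointsError):
            ripley_K(PointPattern(square, [(1, 1)]), RGrid(10, 10))


class TestLTransform:
    def _curve(self, grid, values):
        return SummaryCurve(grid=grid, values=values, estimator="ripley_K")

    def test_csr_expectation_is_zero(self):
        grid = RGrid(10, 10)
        L = L_transform(self._curve(grid, np.pi * grid.r ** 2))
        np.testing.assert_allclose(L.values, 0.0, atol=1e-12)

    def test_empty_circle(self):
        grid = RGrid(5, 5)
        L = L_transform(self._curve(grid, np.zeros(6)))
        assert L.values[-1] == pytest.approx(-5.0)

    def test_known_value(self):
        grid = RGrid(5, 5)
        values = np.zeros(6)
        values[-1] = 100 * np.pi
        L = L_transform(self._curve(grid, values))
        assert L.values[-1] == pytest.approx(5.0)


class TestBivariate:
    def test_single_pair(self, square):
        p = PointPattern(square, [(45, 50), (50, 50)], labels=[1, 2])
        grid = RGrid(20, 20)
        K12 = ripley_K12(p, grid)
        assert np.all(K12.values[grid.r < 5] == 0)
        assert np.all(K12.values[grid.r >= 5] == pytest.approx(square.area))

    def test_coincident_types_attract(self, square, rng):
        pts = rng.random((40, 2)) * 100
        both = np.vstack([pts, pts])
        labels = np.r_[np.ones(40, int), 2 * np.ones(40, int)]
        p = PointPattern(square, both, labels)
        with pytest.warns(UserWarning, match="zero-distance"):
            L12 = L_transform(ripley_K12(p, RGrid(10, 50)))
        assert L12.values[5] > 3.0   # strong attraction at small r

    def test_empty_type_raises(self, square):
        p = PointPattern(square, [(1, 1), (2, 2)], labels=[1, 1])
        with pytest.raises(InsufficientPointsError):
            ripley_K12(p, RGrid(10, 10))

    def test_independent_csr_is_centred(self, square):
        """K12 of two independent CSR patterns averages to pi r^2."""
        grid = RGrid(20, 40)
        acc = np.zeros(grid.n_steps + 1)
        n_rep = 120
        for s in range(n_rep):
            a = simulate_csr(40, square, seed=2 * s).points
            b = simulate_csr(40, square, seed=2 * s + 1).points
            p = PointPattern(square, np.vstack([a, b]),
                             np.r_[np.ones(40, int), 2 * np.ones(40, int)])
            acc += ripley_K12(p, grid).values
        acc /= n_rep
        sel = grid.r >= 5
        rel = np.abs(acc[sel] - np.pi * grid.r[sel] ** 2) \
            / (np.pi * grid.r[sel] ** 2)
        assert rel.max() < 0.05

    def test_random_labeling_identity(self, square):
        """K12 under random labeling of one CSR pattern matches the pooled
        univariate K in expectation."""
        grid = RGrid(15, 30)
        acc12 = np.zeros(grid.n_steps + 1)
        acck = np.zeros(grid.n_steps + 1)
        n_rep = 120
        rng = np.random.default_rng(7)
        for s in range(n_rep):
            pooled = simulate_csr(60, square, seed=900 + s)
            labels = rng.permutation(np.r_[np.ones(30, int),
                                           2 * np.ones(30, int)])
            p = PointPattern(square, pooled.points, labels)
            acc12 += ripley_K12(p, grid).values
            acck += ripley_K(pooled, grid).values
        acc12 /= n_rep
        acck /= n_rep
        sel = grid.r >= 4
        np.testing.assert_allclose(acc12[sel], acck[sel], rtol=0.08)
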