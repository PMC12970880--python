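import numpy as np
import pytest

from grazemark.deposit_io import MarkedPointPattern, StudyWindow, ValidationError
from grazemark.markcorr import (
    DENSITY_CORR,
    R_MARK,
    SCHLATHER,
    DistanceGrid,
    MarkStatisticError,
    box_kernel,
    compute_statistic,
    density_correlation,
    neighbor_counts,
    r_mark_correlation,
    ring_pairs,
    schlather_imm,
)

# ---------------------------------------------------------------------------
# independent naive oracle: plain double loops over ordered pairs, mirroring
# the kernel-ratio formulas term by term (kernel constants kept, not
# cancelled).  Deliberately slow and simple.


def naive_r_mark(pattern, grid):
    pts, m = pattern.points, pattern.marks
    n = pattern.n
    mu = m.mean()
    out = np.full(grid.n_bins, np.nan)
    for b, r in enumerate(grid.r_centers):
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = float(np.hypot(*(pts[i] - pts[j])))
                w = box_kernel(d, r, grid.h)
                num += m[i] * w
                den += w
        if den > 0:
            out[b] = (num / den) / mu
    return out


def naive_schlather(pattern, grid):
    pts, m = pattern.points, pattern.marks
    n = pattern.n
    sigma2 = m.var()
    out = np.full(grid.n_bins, np.nan)
    for b, r in enumerate(grid.r_centers):
        pairs = []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = float(np.hypot(*(pts[i] - pts[j])))
                if box_kernel(d, r, grid.h) > 0:
                    pairs.append((i, j))
        if not pairs:
            continue
        mu_r = np.mean([m[i] for i, _ in pairs])
        prod = np.mean([(m[i] - mu_r) * (m[j] - mu_r) for i, j in pairs])
        out[b] = prod / sigma2
    return out


def naive_density_corr(pattern, grid):
    pts, m = pattern.points, pattern.marks
    n = pattern.n
    out = np.full(grid.n_bins, np.nan)
    for b, r in enumerate(grid.r_centers):
        k = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i != j and float(np.hypot(*(pts[i] - pts[j]))) <= r:
                    k[i] += 1
        if np.all(k == k[0]):
            continue
        mc, kc = m - m.mean(), k - k.mean()
        out[b] = (mc * kc).sum() / np.sqrt((mc**2).sum() * (kc**2).sum())
    return out


NAIVE = {R_MARK: naive_r_mark, SCHLATHER: naive_schlather,
         DENSITY_CORR: naive_density_corr}


class TestBoxKernel:
    def test_inside_band(self):
        assert box_kernel(1.0, 1.0, 0.5) == 1.0

    def test_outside_band(self):
        assert box_kernel(1.6, 1.0, 0.5) == 0.0

    def test_boundary_inclusive(self):
        assert box_kernel(1.5, 1.0, 0.5) == 1.0

    def test_bad_bandwidth(self):
        with pytest.raises(ValidationError):
            box_kernel(1.0, 1.0, 0.0)


class TestRingPairs:
    def test_short_band(self, toy_pattern):
        assert set(ring_pairs(toy_pattern, 1.0, 0.5)) == {(0, 1), (1, 0)}

    def test_long_band(self, toy_pattern):
        assert set(ring_pairs(toy_pattern, 9.0, 0.5)) == {(1, 2), (2, 1)}

    def test_empty_band(self, toy_pattern):
        assert ring_pairs(toy_pattern, 5.0, 0.5) == []

    def test_matches_brute_force(self, make_random_pattern):
        pattern = make_random_pattern(20, seed=5)
        for r in (2.0, 8.0):
            got = set(ring_pairs(pattern, r, 0.5))
            brute = {
                (i, j)
                for i in range(pattern.n)
                for j in range(pattern.n)
                if i != j
                and abs(
                    float(np.hypot(*(pattern.points[i] - pattern.points[j])))
                    - r
                )
                <= 0.5
            }
            assert got == brute


class TestNeighborCounts:
    def test_toy(self, toy_pattern):
        np.testing.assert_array_equal(
            neighbor_counts(toy_pattern, 1.5), [1, 1, 0]
        )

    def test_radius_covers_window(self, toy_pattern):
        np.testing.assert_array_equal(
            neighbor_counts(toy_pattern, 1e6), [2, 2, 2]
        )

    def test_zero_radius(self, toy_pattern):
        np.testing.assert_array_equal(neighbor_counts(toy_pattern, 0.0), [0, 0, 0])


class TestRMark:
    def test_toy_short_bin(self, toy_pattern):
        curve = r_mark_correlation(toy_pattern, DistanceGrid([1.0], 0.5))
        assert curve.values[0] == pytest.approx(0.75, abs=1e-12)

    def test_toy_long_bin(self, toy_pattern):
        curve = r_mark_correlation(toy_pattern, DistanceGrid([9.0], 0.5))
        assert curve.values[0] == pytest.approx(1.25, abs=1e-12)

    def test_constant_marks_give_unity(self, make_random_pattern):
        pattern = make_random_pattern(30, seed=1)
        pattern = pattern.with_marks(np.full(pattern.n, 3.7))
        curve = r_mark_correlation(pattern)
        vals = curve.values[~curve.missing]
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_all_zero_marks_error(self, toy_pattern):
        pattern = toy_pattern.with_marks([0.0, 0.0, 0.0])
        with pytest.raises(MarkStatisticError):
            r_mark_correlation(pattern)

    def test_scale_invariance(self, make_random_pattern):
        pattern = make_random_pattern(25, seed=2)
        a = r_mark_correlation(pattern).values
        b = r_mark_correlation(pattern.with_marks(pattern.marks * 17.3)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_empty_bins_flagged_missing(self, toy_pattern):
        curve = r_mark_correlation(toy_pattern, DistanceGrid([5.0], 0.5))
        assert curve.pair_counts[0] == 0
        assert curve.missing[0]


class TestSchlather:
    def test_toy_short_bin(self, toy_pattern):
        curve = schlather_imm(toy_pattern, DistanceGrid([1.0], 0.5))
        assert curve.values[0] == pytest.approx(-0.375, abs=1e-12)

    def test_colocated_twins_give_unit_correlation(self):
        base = np.array([[10.0 * i, 0.0] for i in range(5)])
        points = np.vstack([base, base])
        marks = np.array([1.0, 2, 3, 4, 5] * 2)
        w = StudyWindow(-1, 41, -1, 1)
        pattern = MarkedPointPattern(w, points, marks)
        curve = schlather_imm(pattern, DistanceGrid([0.5], 0.5))
        assert curve.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_error(self, toy_pattern):
        with pytest.raises(MarkStatisticError):
            schlather_imm(toy_pattern.with_marks([2.0, 2.0, 2.0]))

    def test_affine_invariance(self, make_random_pattern):
        pattern = make_random_pattern(25, seed=3)
        a = schlather_imm(pattern).values
        b = schlather_imm(pattern.with_marks(2.5 * pattern.marks + 40.0)).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_independent_marks_near_zero(self, make_random_pattern):
        # permutation-null expectation at a fixed bin is O(1/n)
        pattern = make_random_pattern(150, seed=4, side=40.0)
        curve = schlather_imm(pattern, DistanceGrid([10.0], 2.0))
        assert abs(curve.values[0]) < 0.2


class TestDensityCorr:
    def test_toy_value(self, toy_pattern):
        curve = density_correlation(toy_pattern, DistanceGrid([1.5], 0.5))
        assert curve.values[0] == pytest.approx(-np.sqrt(3) / 2, abs=1e-12)

    def test_self_correlation(self, make_random_pattern):
        pattern = make_random_pattern(30, seed=6)
        k = neighbor_counts(pattern, 5.5).astype(float)
        if np.all(k == k[0]):  # pragma: no cover - diffuse geometry guard
            pytest.skip("degenerate neighbor counts")
        pattern = pattern.with_marks(k)
        curve = density_correlation(pattern, DistanceGrid([5.5], 0.5))
        assert curve.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_marks_error(self, toy_pattern):
        with pytest.raises(MarkStatisticError):
            density_correlation(toy_pattern.with_marks([1.0, 1.0, 1.0]))

    def test_constant_neighbor_counts_missing(self):
        # equilateral triangle: K identical at every r -> every bin missing
        pts = [[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]
        w = StudyWindow(-1, 2, -1, 2)
        pattern = MarkedPointPattern(w, pts, [1.0, 2.0, 3.0])
        curve = density_correlation(pattern, DistanceGrid([1.0], 0.5))
        assert curve.missing[0]

    def test_affine_invariance_and_bound(self, make_random_pattern):
        pattern = make_random_pattern(40, seed=8)
        a = density_correlation(pattern).values
        b = density_correlation(
            pattern.with_marks(0.3 * pattern.marks + 5.0)
        ).values
        np.testing.assert_allclose(a, b, atol=1e-9)
        assert np.all(np.abs(a[np.isfinite(a)]) <= 1 + 1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_statistics_match_naive(self, make_random_pattern, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        pattern = make_random_pattern(n, seed=seed + 100)
        grid = DistanceGrid(np.arange(0.5, 20.0, 1.0), 0.5)
        for stat, oracle in NAIVE.items():
            got = compute_statistic(pattern, stat, grid).values
            expected = oracle(pattern, grid)
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPermutationNullMoments:
    def test_r_mark_permutation_mean_is_unity(self, make_random_pattern):
        pattern = make_random_pattern(40, seed=11)
        grid = DistanceGrid([3.0, 8.0], 1.0)
        rng = np.random.default_rng(0)
        from grazemark.markcorr import BinnedGeometry

        geom = BinnedGeometry(pattern, grid)
        sims = np.stack([rng.permutation(pattern.marks) for _ in range(800)])
        km = geom.r_mark(sims)
        for b in range(grid.n_bins):
            vals = km[:, b]
            se = vals.std() / np.sqrt(len(vals))
            assert abs(vals.mean() - 1.0) < 3 * se + 1e-9

    def test_mu_bookkeeping_unaffected_by_mean_marked_point(self, toy_pattern):
        # appending a point whose mark equals the current mean keeps mu fixed
        mu = toy_pattern.marks.mean()
        w = toy_pattern.window
        extended = MarkedPointPattern(
            w,
            np.vstack([toy_pattern.points, [[5.0, 0.0]]]),
            np.append(toy_pattern.marks, mu),
        )
        c1 = r_mark_correlation(toy_pattern, DistanceGrid([1.0], 0.5))
        c2 = r_mark_correlation(extended, DistanceGrid([1.0], 0.5))
        assert c1.mark_mean_mu == pytest.approx(c2.mark_mean_mu)


class TestGridAndCurve:
    def test_default_grid(self):
        grid = DistanceGrid.default()
        assert grid.n_bins == 50
        assert grid.r_centers[0] == 0.5
        assert grid.r_centers[-1] == 49.5
        assert grid.h == 0.5

    def test_bad_grid(self):
        with pytest.raises(ValidationError):
            DistanceGrid([2.0, 1.0], 0.5)
        with pytest.raises(ValidationError):
            DistanceGrid([1.0], 0.0)

    def test_curve_export(self, toy_pattern):
        curve = r_mark_correlation(toy_pattern, DistanceGrid([1.0, 5.0], 0.5))
        frame = curve.to_frame()
        assert list(frame.columns) == [
            "statistic", "r_center", "value", "pair_count", "missing_flag",
        ]
        assert frame["missing_flag"].tolist() == [False, True]
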