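"""Row geometry: grouping, line fitting, spacing mode search, Eq.-style counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maizegap.rows import (
    RowLine,
    build_count_report,
    consecutive_distances,
    estimate_spacing,
    expected_count,
    fit_row_line,
    group_rows,
    locate_gaps,
    project_point,
    round_half_up,
)


def spacing_oracle(di, step, tol):
    """Exhaustive candidate-grid enumeration with the smallest-winner rule."""
    di = np.asarray(di, dtype=float)
    grid = list(np.arange(di.min(), di.max() + 1e-9, step))
    if not grid or grid[-1] < di.max() - 1e-9:
        grid.append(di.max())
    best_cnt, best = -1, None
    for dj in grid:
        cnt = sum(1 for d in di if abs(dj - d) < tol)
        if cnt > best_cnt:
            best_cnt, best = cnt, dj
    return best


def line_from_points(points):
    return fit_row_line(np.asarray(points, dtype=float))


class TestGroupRows:
    def test_two_bands(self):
        pts = [(x, 0.0) for x in range(0, 500, 50)] + [(x, 100.0) for x in range(0, 500, 50)]
        groups = group_rows(np.array(pts), 100.0)
        assert sorted(len(g) for g in groups) == [10, 10]

    def test_collinear_points_single_group(self):
        pts = np.array([(x, 2.0 + 0.1 * x) for x in range(0, 120, 12)])
        groups = group_rows(pts, 80.0)
        assert len(groups) == 1

    def test_single_point(self):
        assert len(group_rows(np.array([[3.0, 4.0]]), 50.0)) == 1

    def test_is_partition(self, rng):
        pts = rng.uniform(0, 300, size=(40, 2))
        groups = group_rows(pts, 60.0)
        stacked = np.concatenate(groups)
        assert stacked.shape[0] == pts.shape[0]
        assert sorted(map(tuple, stacked)) == sorted(map(tuple, pts))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_two_partition(self, seed):
        """On two-row fixtures the grouping equals the best 2-partition by
        within-group perpendicular variance, found exhaustively."""
        r = np.random.default_rng(seed)
        n_per = int(r.integers(4, 7))
        spacing = 100.0
        pts = []
        for row in range(2):
            x = np.sort(r.uniform(0, 300, n_per))
            y = row * spacing + r.normal(0, 2.0, n_per)
            pts.extend(zip(x, y))
        pts = np.array(pts)
        n = len(pts)
        best, best_cost = None, np.inf
        for bits in range(1, 2 ** (n - 1)):  # fix point 0 in group A
            a = [i for i in range(n) if not (bits >> i) & 1]
            b = [i for i in range(n) if (bits >> i) & 1]
            if not a or not b:
                continue
            cost = sum(((pts[g, 1] - pts[g, 1].mean()) ** 2).sum() for g in (a, b))
            if cost < best_cost:
                best_cost, best = cost, (a, b)
        oracle = sorted(sorted(map(tuple, pts[list(g)])) for g in best)
        got = sorted(sorted(map(tuple, g)) for g in group_rows(pts, spacing))
        assert got == oracle


class TestFitLine:
    def test_exact_line(self):
        pts = [(x, 2 * x + 1) for x in range(6)]
        line = line_from_points(pts)
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(1.0)
        assert np.allclose(line.residuals(), 0, atol=1e-9)

    def test_two_points_interpolate(self):
        line = line_from_points([(0, 0), (4, 2)])
        assert line.slope == pytest.approx(0.5)
        assert line.intercept == pytest.approx(0.0)

    def test_near_vertical_guard(self):
        pts = [(0.01 * y, y) for y in range(10)]
        line = line_from_points(pts)
        assert line.orientation == "x_of_y"
        assert line.slope == pytest.approx(0.01)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            line_from_points([(1, 1), (1, 1), (1, 1)])

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 100, 20)
        y = 0.3 * x + 7 + rng.normal(0, 1, 20)
        line = line_from_points(np.column_stack([x, y]))
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert line.slope == pytest.approx(beta[0], abs=1e-9)
        assert line.intercept == pytest.approx(beta[1], abs=1e-9)

    def test_residuals_orthogonal_to_regressor(self, rng):
        x = rng.uniform(0, 50, 15)
        y = 1.2 * x - 3 + rng.normal(0, 2, 15)
        line = line_from_points(np.column_stack([x, y]))
        resid = y - (line.slope * x + line.intercept)
        assert abs(resid.sum()) < 1e-8
        assert abs((resid * x).sum()) < 1e-6


class TestProjection:
    def test_point_on_line_is_fixed(self):
        line = line_from_points([(0, 1), (2, 5)])
        p = np.array([1.0, 3.0])
        assert np.allclose(project_point(p, line), p)

    def test_mirror_points_share_foot(self):
        line = line_from_points([(0, 0), (10, 0)])
        assert np.allclose(project_point((3, 4), line), project_point((3, -4), line))

    @given(seed=st.integers(0, 2000))
    @settings(max_examples=40, deadline=None)
    def test_residual_perpendicular_to_direction(self, seed):
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 100, size=(5, 2))
        pts[:, 1] = 0.4 * pts[:, 0] + r.normal(0, 3, 5)
        line = fit_row_line(pts)
        p = r.uniform(0, 100, 2)
        foot = project_point(p, line)
        assert abs((p - foot) @ line.direction) < 1e-9


class TestConsecutiveDistances:
    def test_even_spacing(self):
        line = line_from_points([(0, 0), (25, 0), (50, 0)])
        assert consecutive_distances(line) == pytest.approx([25, 25])

    def test_permutation_invariant(self, rng):
        pts = np.column_stack([rng.permutation(np.arange(0, 200, 20.0)), np.zeros(10)])
        line = fit_row_line(pts)
        line2 = fit_row_line(pts[::-1])
        assert consecutive_distances(line) == pytest.approx(consecutive_distances(line2))


class TestEstimateSpacing:
    def test_single_valued_set(self):
        est = estimate_spacing([50, 50, 50, 50])
        assert est.chosen_Dt == 50
        assert est.refined_Dt == 50

    def test_mode_cluster_beats_outlier(self):
        est = estimate_spacing([48, 52, 49, 51, 100], step_px=1, tolerance=5)
        assert 47 <= est.chosen_Dt <= 52
        assert est.chosen_Dt == spacing_oracle([48, 52, 49, 51, 100], 1, 5)

    def test_tie_broken_to_smallest(self):
        est = estimate_spacing([30, 90], step_px=10, tolerance=5)
        assert est.chosen_Dt == 30

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_spacing([])

    def test_invariants(self):
        est = estimate_spacing([40, 44, 47, 90, 41], step_px=10, tolerance=6)
        assert est.d_min <= est.chosen_Dt <= est.d_max
        assert est.counts.size == est.grid.size
        assert est.counts.max() == est.counts[np.where(est.grid == est.chosen_Dt)][0]

    @given(seed=st.integers(0, 3000))
    @settings(max_examples=50, deadline=None)
    def test_matches_exhaustive_grid(self, seed):
        r = np.random.default_rng(seed)
        di = r.uniform(20, 160, size=int(r.integers(1, 12)))
        tol = float(r.uniform(2, 15))
        est = estimate_spacing(di, step_px=10, tolerance=tol)
        assert est.chosen_Dt == pytest.approx(spacing_oracle(di, 10, tol))


class TestExpectedCount:
    @pytest.mark.parametrize(
        "dd, dt, expected",
        [(225, 25, 10), (0, 25, 1), (230, 25, 10), (237.5, 25, 11)],
    )
    def test_examples(self, dd, dt, expected):
        line = RowLine(0.0, 0.0, "y_of_x", members=np.array([[0.0, 0.0], [dd, 0.0]]))
        line.projections = line.members.copy()
        assert expected_count(line, dt) == expected

    def test_single_plant_row(self):
        line = RowLine(0.0, 0.0, "y_of_x", members=np.array([[5.0, 0.0]]))
        line.projections = line.members.copy()
        assert expected_count(line, 25) == 1

    def test_rejects_nonpositive_dt(self):
        line = line_from_points([(0, 0), (10, 0)])
        with pytest.raises(ValueError):
            expected_count(line, 0)

    def test_nonincreasing_in_dt(self):
        line = line_from_points([(0, 0), (233, 0)])
        counts = [expected_count(line, dt) for dt in np.linspace(10, 120, 40)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(9.2) == 9
        assert round_half_up(-0.5) == 0


class TestLocateGaps:
    def test_single_gap(self):
        line = line_from_points([(0, 0), (25, 0), (75, 0), (100, 0)])
        gaps = locate_gaps(line, 25)
        assert len(gaps) == 1
        interval, n_missing, positions = gaps[0]
        assert n_missing == 1
        assert positions[0][0] == pytest.approx(50)

    def test_no_gaps_at_nominal_spacing(self):
        line = line_from_points([(x, 0) for x in range(0, 125, 25)])
        assert locate_gaps(line, 25) == []

    def test_wide_gap_counts_two(self):
        line = line_from_points([(0, 0), (77, 0)])
        gaps = locate_gaps(line, 25)
        assert gaps[0][1] == 2  # round(77/25) - 1


class TestCountReport:
    def test_clamped_missing(self):
        line = line_from_points([(x, 0) for x in range(0, 250, 25)])
        report = build_count_report([line], 25, detected_count=12)
        assert report.expected_total == 10
        assert report.missing_total == 0

    def test_missing_difference(self):
        line = line_from_points([(x, 0) for x in range(0, 250, 25)])
        report = build_count_report([line], 25, detected_count=8)
        assert report.missing_total == 2

    def test_totals_are_sums(self):
        l1 = line_from_points([(x, 0) for x in range(0, 125, 25)])
        l2 = line_from_points([(x, 100) for x in (0, 25, 75, 100)])
        report = build_count_report([l1, l2], 25, detected_count=9)
        assert report.expected_total == sum(rc.expected for rc in report.per_row)
        assert report.per_row_missing_total == sum(rc.missing for rc in report.per_row)
        assert report.per_row[1].missing == 1
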