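"""Row geometry: row grouping, line fitting, spacing estimation, gap counting.

Plant centroids are grouped into rows, each row is fitted with an ordinary
least-squares line, centroids are projected onto the line, and the average
plant spacing Dt is estimated from the set of consecutive projection gaps Di
by a mode search over a candidate grid (10-px steps from min(Di) to max(Di)).
The expected stand count of a row is ``round(Dd / Dt) + 1`` where Dd is the
span of the projections along the line; missing seedlings are the difference
between expected and detected counts, localized per oversized interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RowLine",
    "SpacingEstimate",
    "RowCount",
    "CountReport",
    "group_rows",
    "fit_row_line",
    "project_point",
    "consecutive_distances",
    "estimate_spacing",
    "expected_count",
    "locate_gaps",
    "build_count_report",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer with 0.5 always rounding up."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# row line fitting and projection


@dataclass
class RowLine:
    """A fitted plant row.

    ``slope``/``intercept`` describe y(x) = slope*x + intercept when
    ``orientation == "y_of_x"``; for near-vertical rows the transposed model
    x(y) is fitted and ``orientation == "x_of_y"``.
    """

    slope: float
    intercept: float
    orientation: str  # "y_of_x" | "x_of_y"
    members: np.ndarray  # (N, 2) centroids (x, y)
    projections: np.ndarray = field(default=None)  # feet of perpendiculars, (N, 2)

    @property
    def anchor(self) -> np.ndarray:
        """A point on the line."""
        if self.orientation == "y_of_x":
            return np.array([0.0, self.intercept])
        return np.array([self.intercept, 0.0])

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the row."""
        if self.orientation == "y_of_x":
            d = np.array([1.0, self.slope])
        else:
            d = np.array([self.slope, 1.0])
        return d / np.hypot(d[0], d[1])

    @property
    def span(self) -> float:
        """Dd: distance between the two extreme projections along the line."""
        t = self.member_coordinates()
        if t.size == 0:
            return 0.0
        return float(t.max() - t.min())

    def member_coordinates(self) -> np.ndarray:
        """1-D coordinates of the member projections along the line."""
        return (self.members - self.anchor) @ self.direction

    def residuals(self) -> np.ndarray:
        """Perpendicular residual vectors member - projection."""
        return self.members - self.projections


def fit_row_line(points: np.ndarray) -> RowLine:
    """Ordinary least squares line through a row of centroids.

    Minimizes the vertical sum of squares sum_i (y_i - a x_i - b)^2; for
    steep rows (x-spread below half the y-spread) the transposed model x(y)
    is fitted instead, so near-vertical rows stay well-conditioned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (x, y) points")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points identical; no line is defined")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) >= 0.5 * np.ptp(y):
        slope, intercept = np.polyfit(x, y, 1)
        line = RowLine(float(slope), float(intercept), "y_of_x", pts)
    else:
        slope, intercept = np.polyfit(y, x, 1)
        line = RowLine(float(slope), float(intercept), "x_of_y", pts)
    line.projections = np.array([project_point(p, line) for p in pts])
    return line


def project_point(point: np.ndarray, line: RowLine) -> np.ndarray:
    """Foot of the perpendicular from ``point`` to the row line."""
    p = np.asarray(point, dtype=float)
    a, d = line.anchor, line.direction
    return a + ((p - a) @ d) * d


def consecutive_distances(row: RowLine) -> np.ndarray:
    """Gaps Di between consecutive projection points along the row.

    Projections are sorted by their 1-D coordinate along the line; the
    result has N - 1 entries (empty for a single-member row) and is
    invariant to the input ordering of the members.
    """
    t = np.sort(row.member_coordinates())
    if t.size < 2:
        return np.empty(0)
    return np.diff(t)


# ---------------------------------------------------------------------------
# spacing mode search


@dataclass
class SpacingEstimate:
    """Result of the plant-spacing mode search.

    ``chosen_Dt`` is the smallest candidate Dj attaining the maximal match
    counter CNTj = #{i : |Dj - Di| < tolerance}. ``refined_Dt`` averages the
    Di inside the tolerance window around the chosen candidate, removing the
    grid quantization of the 10-px candidate step.
    """

    distances: np.ndarray  # Di
    d_min: float
    d_max: float
    grid: np.ndarray  # Dj candidates
    counts: np.ndarray  # CNTj
    tolerance: float
    chosen_Dt: float
    refined_Dt: float


def estimate_spacing(
    distances: np.ndarray,
    step_px: float = 10.0,
    tolerance: float | None = None,
) -> SpacingEstimate:
    """Mode search for the average plant spacing.

    Candidates Dj run from min(Di) to max(Di) in ``step_px`` steps (the
    maximum is appended when the grid does not land on it). Each candidate
    counts the Di within ``tolerance`` of it; the smallest candidate with the
    maximal count wins, which biases ties toward the unit spacing rather
    than its multiples across emergence gaps.

    ``tolerance`` defaults to 0.2 x median(Di).
    """
    di = np.asarray(distances, dtype=float).ravel()
    if di.size == 0:
        raise ValueError("empty distance set; no spacing estimable")
    if step_px <= 0:
        raise ValueError("step_px must be > 0")
    if tolerance is None:
        tolerance = 0.2 * float(np.median(di))
    if tolerance <= 0:
        tolerance = max(step_px / 2.0, 1e-9)
    d_min, d_max = float(di.min()), float(di.max())
    grid = np.arange(d_min, d_max + 1e-9, step_px)
    if grid.size == 0 or grid[-1] < d_max - 1e-9:
        grid = np.append(grid, d_max)
    counts = np.array([(np.abs(dj - di) < tolerance).sum() for dj in grid])
    idx = int(np.argmax(counts))  # argmax returns the first (= smallest Dj)
    chosen = float(grid[idx])
    window = di[np.abs(di - chosen) < tolerance]
    refined = float(window.mean()) if window.size else chosen
    return SpacingEstimate(di, d_min, d_max, grid, counts, float(tolerance), chosen, refined)


# ---------------------------------------------------------------------------
# expected counts and gap localization


def expected_count(row: RowLine, dt: float) -> int:
    """Expected stand count of a row: round(Dd / Dt) + 1 (half-up).

    A single-member row has zero span and therefore expects one plant.
    """
    if dt <= 0:
        raise ValueError("Dt must be > 0")
    return round_half_up(row.span / dt) + 1


def locate_gaps(
    row: RowLine, dt: float, gap_factor: float = 1.5
) -> list[tuple[int, int, list[tuple[float, float]]]]:
    """Find oversized inter-plant intervals and infer the missing positions.

    For each consecutive gap Di > gap_factor * Dt the number of missing
    plants is round(Di / Dt) - 1 and their positions are evenly interpolated
    on the line segment between the two flanking projections.

    Returns a list of (interval index, n_missing, midpoint positions).
    """
    if dt <= 0:
        raise ValueError("Dt must be > 0")
    t = row.member_coordinates()
    order = np.argsort(t)
    t_sorted = t[order]
    gaps: list[tuple[int, int, list[tuple[float, float]]]] = []
    a, d = row.anchor, row.direction
    for i in range(t_sorted.size - 1):
        di = t_sorted[i + 1] - t_sorted[i]
        if di > gap_factor * dt:
            n_missing = round_half_up(di / dt) - 1
            if n_missing < 1:
                continue
            positions = []
            for j in range(1, n_missing + 1):
                tj = t_sorted[i] + di * j / (n_missing + 1)
                p = a + tj * d
                positions.append((float(p[0]), float(p[1])))
            gaps.append((i, n_missing, positions))
    return gaps


@dataclass
class RowCount:
    index: int
    detected: int
    expected: int
    missing: int
    gaps: list = field(default_factory=list)


@dataclass
class CountReport:
    """Detected vs expected seedling counts for one image.

    ``missing_total`` is the image-level count max(0, expected - detected);
    ``per_row_missing_total`` sums the per-interval gap attribution. The two
    need not agree (end-of-row gaps are invisible to the span-based expected
    count) and both are reported.
    """

    per_row: list[RowCount]
    detected_total: int
    expected_total: int
    missing_total: int
    per_row_missing_total: int
    dt_used: float
    spacing: SpacingEstimate | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "detected_total": self.detected_total,
            "expected_total": self.expected_total,
            "missing_total": self.missing_total,
            "per_row_missing_total": self.per_row_missing_total,
            "dt_used": self.dt_used,
            "rounding": "half-up",
            "flags": list(self.flags),
            "per_row": [
                {
                    "row": rc.index,
                    "detected": rc.detected,
                    "expected": rc.expected,
                    "missing": rc.missing,
                    "gaps": [
                        {"interval": gi, "n_missing": nm, "positions": pos}
                        for gi, nm, pos in rc.gaps
                    ],
                }
                for rc in self.per_row
            ],
        }


def build_count_report(
    rows: list[RowLine],
    dt: float,
    detected_count: int,
    gap_factor: float = 1.5,
    spacing: SpacingEstimate | None = None,
) -> CountReport:
    """Assemble the per-row and image-level missing-seedling report."""
    if detected_count < 0:
        raise ValueError("detected_count must be >= 0")
    per_row: list[RowCount] = []
    for k, row in enumerate(rows):
        gaps = locate_gaps(row, dt, gap_factor)
        exp = expected_count(row, dt)
        det = int(row.members.shape[0])
        per_row.append(RowCount(k, det, exp, sum(g[1] for g in gaps), gaps))
    expected_total = sum(rc.expected for rc in per_row)
    return CountReport(
        per_row=per_row,
        detected_total=int(detected_count),
        expected_total=expected_total,
        missing_total=max(0, expected_total - int(detected_count)),
        per_row_missing_total=sum(rc.missing for rc in per_row),
        dt_used=float(dt),
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# row grouping


def _split_1d(sorted_values: np.ndarray, gap: float) -> list[np.ndarray]:
    """Split a sorted 1-D array into runs wherever a gap exceeds ``gap``."""
    if sorted_values.size == 0:
        return []
    breaks = np.where(np.diff(sorted_values) > gap)[0]
    return np.split(np.arange(sorted_values.size), breaks + 1)


def _cluster_along(perp: np.ndarray, gap: float) -> tuple[list[np.ndarray], float, float]:
    """Cluster perpendicular coordinates; return (clusters, score, max range)."""
    order = np.argsort(perp, kind="stable")
    runs = _split_1d(perp[order], gap)
    clusters = [order[r] for r in runs]
    score = 0.0
    max_range = 0.0
    for c in clusters:
        vals = perp[c]
        score += float(((vals - vals.mean()) ** 2).sum())
        max_range = max(max_range, float(np.ptp(vals)))
    return clusters, score, max_range


def _core_mask(perp: np.ndarray, eps: float, min_neighbors: int) -> np.ndarray:
    """Points with at least ``min_neighbors`` others within +-eps (1-D).

    Plant rows are dense bands in the perpendicular coordinate; sparse
    clutter (weeds between rows) is not, and is set aside so it can
    neither bridge two rows into one cluster nor distort the row
    direction score.
    """
    order = np.argsort(perp, kind="stable")
    s = perp[order]
    lo = np.searchsorted(s, s - eps, side="left")
    hi = np.searchsorted(s, s + eps, side="right")
    core_sorted = (hi - lo - 1) >= min_neighbors
    mask = np.zeros(perp.size, dtype=bool)
    mask[order] = core_sorted
    return mask


def group_rows(centroids: np.ndarray, expected_row_spacing_px: float) -> list[np.ndarray]:
    """Partition centroids into plant rows.

    The dominant row direction is taken from the candidate angle whose
    perpendicular-coordinate clustering (split where the gap between sorted
    coordinates exceeds half the expected row spacing) yields tight,
    row-like bands; candidates are the two principal axes of the centroid
    covariance plus a fine angular scan. Among candidates whose clusters are
    all narrower than 0.6 x the expected spacing, the fewest clusters (then
    the lowest within-cluster variance) win — rows hold many plants whereas
    across-row groupings fragment into many small clusters.

    When enough points are available, low-density points (fewer than 3
    neighbors within 0.15 x the row spacing in the perpendicular
    coordinate) are treated as inter-row clutter: they are excluded from
    clustering and direction scoring and come back as singleton groups, so
    the output is still a partition of the input. Downstream stages drop
    groups below their minimum row membership.

    Returns a list of (n_k, 2) arrays of centroids, ordered by the mean
    perpendicular coordinate of each group.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("need at least one centroid")
    if pts.shape[0] == 1:
        return [pts.copy()]
    if expected_row_spacing_px <= 0:
        raise ValueError("expected_row_spacing_px must be > 0")

    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    pca_angles = [math.atan2(v[1], v[0]) for v in vecs.T]
    candidates = sorted(
        {round(a % math.pi, 6) for a in pca_angles}
        | {round(math.radians(a), 6) for a in np.arange(0.0, 180.0, 1.0)}
    )

    gap = 0.5 * expected_row_spacing_px
    eps = 0.15 * expected_row_spacing_px
    use_density = pts.shape[0] >= 8
    best = None  # key, core clusters (index arrays), clutter indices, angle
    for theta in candidates:
        # perpendicular coordinate w.r.t. a row direction at angle theta
        perp = pts @ np.array([-math.sin(theta), math.cos(theta)])
        if use_density:
            core = _core_mask(perp, eps, 3)
            if not core.any():
                core = np.ones(perp.size, dtype=bool)
        else:
            core = np.ones(perp.size, dtype=bool)
        core_idx = np.where(core)[0]
        clusters, score, max_range = _cluster_along(perp[core_idx], gap)
        clusters = [core_idx[c] for c in clusters]
        invalid = int(max_range > 0.6 * expected_row_spacing_px)
        key = (invalid, (~core).sum(), len(clusters), score)
        if best is None or key < best[0]:
            best = (key, clusters, np.where(~core)[0], theta)
    _, clusters, clutter, theta = best
    normal = np.array([-math.sin(theta), math.cos(theta)])
    groups = clusters + [np.array([i]) for i in clutter]
    groups = sorted(groups, key=lambda idx: float((pts[idx] @ normal).mean()))
    return [pts[idx] for idx in groups]
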