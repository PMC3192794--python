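"""Tukey halfspace depth and the bagplot, a bivariate boxplot.

The halfspace (Tukey) depth of a point relative to a 2-D cloud is the
smallest number of cloud points contained in any closed halfplane through
the point — a bivariate extension of univariate rank. The bagplot
summarizes a cloud by its depth median (deepest location), a "bag"
containing the deepest half of the points, and a fence (the bag inflated
threefold about the median) beyond which points are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon


def halfspace_depth(points: np.ndarray, queries: np.ndarray | None = None) -> np.ndarray:
    """Exact 2-D Tukey halfspace depth of each query point w.r.t. ``points``.

    For a query p, the depth is min over closed halfplanes through p of the
    number of cloud points they contain. The minimum is attained just past
    a direction perpendicular to some p-to-point vector, so evaluating the
    count at all such critical directions (nudged both ways) is exact for
    points in general position.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if queries is None:
        queries = pts
    queries = np.asarray(queries, dtype=float).reshape(-1, 2)
    n = len(pts)
    scale = max(np.abs(pts).max(), 1.0)
    tol = 1e-9 * scale
    eps = 1e-7  # angular nudge past each critical direction
    depths = np.empty(len(queries), dtype=int)
    for qi, p in enumerate(queries):
        d = pts - p
        r = np.hypot(d[:, 0], d[:, 1])
        coincident = int((r <= tol).sum())  # always inside any closed halfplane
        live = d[r > tol]
        if len(live) == 0:
            depths[qi] = coincident
            continue
        phi = np.arctan2(live[:, 1], live[:, 0])
        crit = np.concatenate([phi + np.pi / 2, phi - np.pi / 2])
        angles = np.concatenate([crit - eps, crit + eps])
        u = np.column_stack([np.cos(angles), np.sin(angles)])
        proj = u @ live.T  # (directions, points)
        counts = (proj >= -tol).sum(axis=1)
        depths[qi] = int(counts.min()) + coincident
    return depths


@dataclass
class BagplotSummary:
    """Depth median, 50% bag, fence and outliers of a 2-D point cloud."""

    median: np.ndarray
    depths: np.ndarray
    bag: np.ndarray | None  # hull vertices of the deepest half, or None if degenerate
    fence: np.ndarray | None
    outlier_indices: list[int] = field(default_factory=list)
    degenerate: bool = False


def bagplot_summary(points: np.ndarray) -> BagplotSummary:
    """Bagplot summary of a 2-D cloud.

    The depth median is the deepest point (centroid of the deepest set on
    ties); the bag is the convex hull of the deepest ``ceil(n/2)`` points;
    the fence inflates the bag by a factor 3 about the median; points
    outside the fence are outliers. Collinear clouds have no 2-D bag and
    are returned with the ``degenerate`` flag set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 3:
        raise ValueError("bagplot needs at least 3 points")
    depths = halfspace_depth(pts)
    deepest = pts[depths == depths.max()]
    median = deepest.mean(axis=0)

    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(np.abs(centered).max(), 1.0)) < 2:
        return BagplotSummary(
            median=median, depths=depths, bag=None, fence=None, degenerate=True
        )
    k = int(np.ceil(n / 2))
    order = np.lexsort((np.arange(n), -depths))  # depth desc, stable by index
    bag_points = pts[order[:k]]
    from scipy.spatial import ConvexHull

    hull = ConvexHull(bag_points)
    bag = bag_points[hull.vertices]
    fence = median + 3.0 * (bag - median)
    fence_poly = Polygon(fence).buffer(1e-9 * max(np.abs(pts).max(), 1.0))
    outliers = [
        int(i) for i, p in enumerate(pts) if not fence_poly.contains(Point(p))
    ]
    return BagplotSummary(
        median=median,
        depths=depths,
        bag=bag,
        fence=fence,
        outlier_indices=outliers,
        degenerate=False,
    )
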