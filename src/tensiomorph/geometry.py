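"""Small planar-geometry utilities shared across modules.

Polygon metrics (shoelace area, perimeter, circularity, convexity
deficiency, second-moment ellipse) and point-to-polyline distances used
by contour QC, cell-shape metrics and the ADSA objective.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "polygon_area",
    "polygon_perimeter",
    "polyline_length",
    "circularity",
    "convexity_deficiency",
    "ellipse_axes",
    "point_polyline_distances",
    "is_self_intersecting",
]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) point array, got shape {pts.shape}")
    return pts


def polygon_area(points) -> float:
    """Unsigned shoelace area of a closed polygon (closing edge implied)."""
    p = _as_points(points)
    x, y = p[:, 0], p[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def signed_polygon_area(points) -> float:
    p = _as_points(points)
    x, y = p[:, 0], p[:, 1]
    return float((np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polygon_perimeter(points) -> float:
    """Perimeter of a closed polygon (closing edge included)."""
    p = _as_points(points)
    d = np.diff(np.vstack([p, p[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polyline_length(points, closed: bool = False) -> float:
    """Total Euclidean length of a polyline; closing segment iff ``closed``."""
    p = _as_points(points)
    if closed:
        return polygon_perimeter(p)
    d = np.diff(p, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def circularity(points) -> float:
    """Isoperimetric ratio 4*pi*A/P^2; 1 for a circle, < 1 otherwise."""
    a = polygon_area(points)
    per = polygon_perimeter(points)
    if per == 0:
        raise ValueError("degenerate polygon with zero perimeter")
    return 4.0 * np.pi * a / per**2


def convexity_deficiency(points) -> float:
    """1 - A/A_hull: zero for convex outlines, grows with concavity."""
    p = _as_points(points)
    hull = ConvexHull(p)
    a_hull = hull.volume  # 2-D: "volume" is area
    if a_hull == 0:
        raise ValueError("degenerate polygon with zero hull area")
    return max(0.0, 1.0 - polygon_area(p) / a_hull)


def ellipse_axes(points) -> tuple[float, float]:
    """(major, minor) axis lengths of the second-moment equivalent ellipse.

    The ellipse with the same area-normalized second central moments as
    the polygon's vertex set (uniform vertex weighting — adequate for the
    densely, regularly sampled outlines produced by tracing).
    """
    p = _as_points(points)
    q = p - p.mean(axis=0)
    cov = np.cov(q.T)
    w = np.sort(np.linalg.eigvalsh(cov))[::-1]
    w = np.clip(w, 0.0, None)
    # for a uniform ellipse outline, var along axis a is a^2/2
    major = 2.0 * np.sqrt(2.0 * w[0])
    minor = 2.0 * np.sqrt(2.0 * w[1])
    return float(major), float(minor)


def point_polyline_distances(points, polyline) -> np.ndarray:
    """Distance from each query point to a polyline (open chain).

    Dense-vertex KD-tree lookup, then exact refinement against the two
    segments adjacent to the nearest vertex.
    """
    q = _as_points(points)
    v = _as_points(polyline)
    tree = cKDTree(v)
    best, idx = tree.query(q)
    for off in (-1, 0):
        j = idx + off
        valid = (j >= 0) & (j < len(v) - 1)
        if not valid.any():
            continue
        a = v[j[valid]]
        ab = v[j[valid] + 1] - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", q[valid] - a, ab) / denom, 0.0, 1.0)
        diff = a + t[:, None] * ab - q[valid]
        best[valid] = np.minimum(best[valid], np.hypot(diff[:, 0], diff[:, 1]))
    return best


def _point_segment_distance(p, a, b) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(p - a)))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t * ab
    return float(np.hypot(*(p - proj)))


def is_self_intersecting(points, closed: bool = True) -> bool:
    """Brute-force segment-pair crossing test (fine for traced outlines)."""
    p = _as_points(points)
    segs = np.vstack([p, p[:1]]) if closed else p
    n = len(segs) - 1

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        a1, a2 = segs[i], segs[i + 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1 and closed:
                continue  # shared endpoint of closing edge
            b1, b2 = segs[j], segs[j + 1]
            d1 = cross(a1, a2, b1)
            d2 = cross(a1, a2, b2)
            d3 = cross(b1, b2, a1)
            d4 = cross(b1, b2, a2)
            # strict crossings only: endpoint touching is not an intersection
            if d1 * d2 < 0 and d3 * d4 < 0:
                return True
    return False
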