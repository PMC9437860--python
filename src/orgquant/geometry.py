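"""Shared polygon/polyline geometry primitives.

All polygons are (N, 2) float arrays of (x, y) vertices, implicitly closed
(last vertex joins the first). Point-in-polygon uses the even-odd rule.
"""
from __future__ import annotations

import numpy as np


def polygon_perimeter(points: np.ndarray, closed: bool = True) -> float:
    """Arc length of a polyline; includes the closing segment if ``closed``."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        return 0.0
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    if closed:
        d += float(np.linalg.norm(pts[0] - pts[-1]))
    return float(d)


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) containment test, vectorized over points.

    Points exactly on an edge are classified by the crossing parity of the
    horizontal ray; this is deterministic but edge-sensitive, which is fine
    for pixel centers against sub-pixel polygons.
    """
    pts = np.asarray(points, dtype=np.float64)
    poly = np.asarray(polygon, dtype=np.float64)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        crosses = (y0 > y) != (y1 > y)
        if np.any(crosses):
            xc = x[crosses]
            yc = y[crosses]
            x_at = (x1 - x0) * (yc - y0) / (y1 - y0) + x0
            hit = np.zeros(len(pts), dtype=bool)
            hit[crosses] = xc < x_at
            inside ^= hit
        x0, y0 = x1, y1
    return inside


def point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each point to segment ``a``-``b``."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def point_polygon_distance(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Distance from each point to the closed polygon boundary."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    poly = np.asarray(polygon, dtype=np.float64)
    best = np.full(len(pts), np.inf)
    for i in range(len(poly)):
        a = poly[i]
        b = poly[(i + 1) % len(poly)]
        np.minimum(best, point_segment_distance(pts, a, b), out=best)
    return best


def farthest_pair(points: np.ndarray) -> tuple[int, int]:
    """Indices (i, j), i < j, of the two mutually farthest points.

    Ties are broken by the lexicographically smallest (i, j). Uses the convex
    hull for large inputs; falls back to the O(n^2) sweep when the hull is
    degenerate (collinear input).
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    cand = np.arange(n)
    if n > 600:
        try:
            from scipy.spatial import ConvexHull

            cand = np.sort(ConvexHull(pts).vertices)
        except Exception:  # collinear / degenerate input
            cand = np.arange(n)
    sub = pts[cand]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
    iu, ju = np.triu_indices(len(sub), k=1)
    dists = d2[iu, ju]
    best = dists.max()
    # exact-equality ties resolved by smallest (i, j) in original indexing
    mask = dists == best
    gi = cand[iu[mask]]
    gj = cand[ju[mask]]
    order = np.lexsort((gj, gi))
    return int(gi[order[0]]), int(gj[order[0]])


def _rdp_open(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Douglas-Peucker on an open chain; returns a boolean keep-mask.

    Iterative (explicit stack) so long pixel chains cannot hit the
    recursion limit.
    """
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        seg = points[lo + 1 : hi]
        d = point_segment_distance(seg, points[lo], points[hi])
        k = int(np.argmax(d))  # first max wins -> deterministic
        if d[k] > epsilon:
            mid = lo + 1 + k
            keep[mid] = True
            stack.append((lo, mid))
            stack.append((mid, hi))
    return keep


def simplify_open(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Douglas-Peucker simplification of an open polyline."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        return pts.copy()
    return pts[_rdp_open(pts, epsilon)]


def simplify_closed(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Douglas-Peucker simplification of a closed chain.

    The recursion is seeded with the two mutually farthest points (ties by
    lowest index); each of the two open sub-chains between them is simplified
    independently and the results are concatenated. The returned vertices are
    a subset of the input points and every input point lies within
    ``epsilon`` of the returned polygon. The result may have as few as 2
    vertices when all excursions are below ``epsilon``.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n <= 2:
        return pts.copy()
    i, j = farthest_pair(pts)
    chain1 = pts[i : j + 1]
    chain2 = np.concatenate([pts[j:], pts[: i + 1]], axis=0)
    out1 = simplify_open(chain1, epsilon)
    out2 = simplify_open(chain2, epsilon)
    return np.concatenate([out1[:-1], out2[:-1]], axis=0)


def is_simple_polygon(polygon: np.ndarray) -> bool:
    """True if the closed polygon has no self-intersections (shapely check)."""
    from shapely.geometry import Polygon

    try:
        return bool(Polygon(np.asarray(polygon, dtype=np.float64)).is_valid)
    except Exception:
        return False
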