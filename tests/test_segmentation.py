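import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgquant.errors import (
    ClusterTooSmallError,
    DegenerateContourError,
    ParameterError,
)
from orgquant.images import IntensityImage
from orgquant.segmentation import (
    CellCluster,
    approximate_contour,
    binarize,
    clean_clusters,
    erode_mask,
    label_clusters,
    segment_cells,
    trace_boundary,
)

from conftest import make_disk_mask, random_blob_mask

# ---------------------------------------------------------------- oracles


def brute_force_erode(mask, radius):
    """Erosion by explicit structuring-element sweep (disk of given radius)."""
    from skimage.morphology import disk

    se = disk(radius).astype(bool)
    k = radius
    h, w = mask.shape
    out = np.zeros_like(mask)
    offs = np.argwhere(se) - k
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                    ok = False
                    break
            out[r, c] = ok
    return out


def brute_force_otsu(values):
    """Exhaustive threshold search maximizing between-class variance."""
    vals = np.asarray(values, dtype=float).ravel()
    best_t, best_var = None, -1.0
    for t in np.unique(vals)[:-1]:
        lo = vals[vals <= t]
        hi = vals[vals > t]
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def flood_fill_components(mask, connectivity):
    """Brute-force flood fill; returns list of pixel-coordinate sets."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    rr, cc = stack.pop()
                    comp.add((cc, rr))  # (x, y)
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def boundary_pixel_set(mask):
    """{true pixels with >= 1 false 4-neighbor}, border counts as false."""
    h, w = mask.shape
    out = set()
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                    out.add((c, r))
                    break
    return out


def reference_rdp_open(points, eps):
    """Textbook recursive Douglas-Peucker on an open chain."""

    def seg_dist(p, a, b):
        ab = b - a
        denom = ab @ ab
        if denom == 0:
            return np.linalg.norm(p - a)
        t = np.clip((p - a) @ ab / denom, 0, 1)
        return np.linalg.norm(p - (a + t * ab))

    points = np.asarray(points, float)
    if len(points) < 3:
        return points
    dmax, idx = -1.0, 0
    for i in range(1, len(points) - 1):
        d = seg_dist(points[i], points[0], points[-1])
        if d > dmax:
            dmax, idx = d, i
    if dmax > eps:
        left = reference_rdp_open(points[: idx + 1], eps)
        right = reference_rdp_open(points[idx:], eps)
        return np.vstack([left[:-1], right])
    return np.vstack([points[0], points[-1]])


def reference_rdp_closed(points, eps):
    """Closed-chain DP seeded at the mutually farthest pair (ties lowest index)."""
    points = np.asarray(points, float)
    n = len(points)
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(points[i] - points[j])
            if d > best[0]:
                best = (d, (i, j))
    i, j = best[1]
    c1 = points[i : j + 1]
    c2 = np.vstack([points[j:], points[: i + 1]])
    o1 = reference_rdp_open(c1, eps)
    o2 = reference_rdp_open(c2, eps)
    return np.vstack([o1[:-1], o2[:-1]])


# ------------------------------------------------------------- erode_mask


class TestErodeMask:
    def test_all_true_radius1_keeps_interior(self):
        m = np.ones((10, 10), dtype=bool)
        e = erode_mask(m, 1)
        expected = np.zeros((10, 10), dtype=bool)
        expected[1:9, 1:9] = True
        assert np.array_equal(e, expected)

    def test_isolated_pixel_vanishes(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        assert not erode_mask(m, 1).any()

    def test_bridge_removed_matches_brute_force(self):
        m = np.zeros((7, 13), dtype=bool)
        m[1:6, 1:6] = True
        m[1:6, 7:12] = True
        m[3, 6] = True  # 1-px bridge
        e = erode_mask(m, 1)
        assert np.array_equal(e, brute_force_erode(m, 1))
        assert len(label_clusters(e, 8)) == 2

    def test_radius_zero_identity(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert np.array_equal(erode_mask(m, 0), m)

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            erode_mask(np.ones((3, 3), dtype=bool), -1)

    @given(st.integers(0, 2**25 - 1), st.integers(0, 2))
    @settings(max_examples=25, deadline=None)
    def test_anti_extensive_and_idempotent_zero(self, seed, radius):
        m = np.random.default_rng(seed).random((12, 12)) > 0.5
        e = erode_mask(m, radius)
        assert not (e & ~m).any()  # output subset of input
        assert np.array_equal(erode_mask(e, 0), e)

    def test_matches_brute_force_random(self, rng):
        for _ in range(3):
            m = rng.random((15, 15)) > 0.4
            for radius in (1, 2):
                assert np.array_equal(
                    erode_mask(m, radius), brute_force_erode(m, radius)
                )


# --------------------------------------------------------------- binarize


class TestBinarize:
    def test_zeros_fixed_zero_strict(self):
        img = IntensityImage(np.zeros((4, 4)))
        assert not binarize(img, "fixed", 0.0).any()

    def test_two_level_otsu(self):
        px = np.full((10, 10), 10.0)
        px[3:7, 3:7] = 200.0
        got = binarize(IntensityImage(px), "otsu")
        assert np.array_equal(got, px > brute_force_otsu(px))
        assert np.array_equal(got, px == 200.0)

    def test_fixed_below_min_all_true(self):
        img = IntensityImage(np.full((3, 3), 5.0))
        assert binarize(img, "fixed", 4.0).all()

    def test_constant_otsu_warns_all_false(self):
        img = IntensityImage(np.full((5, 5), 7.0))
        with pytest.warns(UserWarning):
            assert not binarize(img, "otsu").any()

    def test_fixed_requires_threshold(self):
        with pytest.raises(ParameterError):
            binarize(IntensityImage(np.zeros((3, 3))), "fixed")


# --------------------------------------------------------- label_clusters


class TestLabelClusters:
    def test_empty_mask(self):
        assert label_clusters(np.zeros((4, 4), dtype=bool), 8) == []

    def test_diagonal_connectivity(self):
        m = np.array([[1, 0], [0, 1]], dtype=bool)
        assert len(label_clusters(m, 4)) == 2
        assert len(label_clusters(m, 8)) == 1

    def test_size_sorted_matches_flood_fill(self):
        m = np.zeros((40, 40), dtype=bool)
        m[1:11, 1:6] = True  # 50
        m[15:18, 15:18] = True  # 9
        m[20:30, 20:40] = True  # 200
        clusters = label_clusters(m, 8)
        assert [c.area for c in clusters] == [200, 50, 9]
        assert [c.label for c in clusters] == [1, 2, 3]
        oracle = sorted(flood_fill_components(m, 8), key=len, reverse=True)
        for c, comp in zip(clusters, oracle):
            assert c.pixel_set == comp

    def test_partition_property(self, rng):
        m = rng.random((30, 30)) > 0.55
        clusters = label_clusters(m, 8)
        union = set()
        total = 0
        for c in clusters:
            assert not (union & c.pixel_set)  # pairwise disjoint
            union |= c.pixel_set
            total += c.area
        assert total == int(m.sum())
        assert union == {(x, y) for y, x in np.argwhere(m)}

    def test_bad_connectivity(self):
        with pytest.raises(ParameterError):
            label_clusters(np.ones((2, 2), dtype=bool), 6)


# --------------------------------------------------------- clean_clusters


def enclosed_pixels(mask):
    """Exhaustive enclosed-pixel test: false pixels not 4-connected to border."""
    from scipy import ndimage as ndi

    outside = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if (r in (0, h - 1) or c in (0, w - 1)) and not mask[r, c]
    ]
    for r, c in stack:
        outside[r, c] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                stack.append((rr, cc))
    return ~mask & ~outside


class TestCleanClusters:
    def test_annulus_filled_to_disk(self):
        outer = make_disk_mask((25, 25), (12, 12), 10)
        inner = make_disk_mask((25, 25), (12, 12), 4)
        ring = outer & ~inner
        [cleaned] = clean_clusters(label_clusters(ring, 8), min_area=1)
        assert cleaned.area == int(outer.sum())
        expected = ring | enclosed_pixels(ring)
        assert np.array_equal(cleaned.mask, expected)

    def test_small_cluster_removed(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:7, 2:10] = True  # area 40
        assert clean_clusters(label_clusters(m, 8), min_area=100) == []

    def test_post_fill_no_holes(self, rng):
        m = rng.random((30, 30)) > 0.45
        for c in clean_clusters(label_clusters(m, 8), min_area=5):
            assert not enclosed_pixels(c.mask).any()
            assert c.area >= 5


# --------------------------------------------------------- trace_boundary


class TestTraceBoundary:
    def test_3x3_block(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        b = trace_boundary(CellCluster(1, m))
        assert len(b) == 8
        assert {tuple(p) for p in b} == boundary_pixel_set(m)
        # CCW in mathematical (x, y) orientation: positive shoelace area
        x, y = b[:, 0].astype(float), b[:, 1].astype(float)
        assert np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y) > 0
        # consecutive points are 8-adjacent, including closure
        d = np.abs(np.diff(np.vstack([b, b[:1]]), axis=0)).max(axis=1)
        assert (d == 1).all()

    def test_line_cluster_degenerate_chain(self):
        m = np.zeros((3, 7), dtype=bool)
        m[1, 1:6] = True
        b = trace_boundary(CellCluster(1, m))
        assert len(b) == 5
        assert {tuple(p) for p in b} == {(x, 1) for x in range(1, 6)}

    def test_too_small(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        with pytest.raises(ClusterTooSmallError):
            trace_boundary(CellCluster(1, m))

    def test_random_blob_matches_brute_force(self, rng):
        for _ in range(5):
            m = random_blob_mask(rng)
            b = trace_boundary(CellCluster(1, m))
            assert {tuple(p) for p in b} == boundary_pixel_set(m)
            assert len(b) == len({tuple(p) for p in b})  # no duplicates


# ---------------------------------------------------- approximate_contour


class TestApproximateContour:
    def test_rectangle_keeps_corners(self):
        pts = []
        for x in range(0, 20):
            pts.append((x, 0))
        for y in range(0, 10):
            pts.append((19, y))
        for x in range(19, -1, -1):
            pts.append((x, 9))
        for y in range(9, 0, -1):
            pts.append((0, y))
        contour = approximate_contour(np.array(pts, float), epsilon_rel=0.009)
        assert contour.n_vertices == 4
        assert {tuple(v) for v in contour.vertices} == {
            (0.0, 0.0),
            (19.0, 0.0),
            (19.0, 9.0),
            (0.0, 9.0),
        }

    def test_circle_epsilon_bound(self):
        from orgquant.geometry import point_polygon_distance

        th = np.linspace(0, 2 * np.pi, 629)[:-1]
        pts = np.column_stack([100 * np.cos(th), 100 * np.sin(th)])
        contour = approximate_contour(pts, epsilon_rel=0.009)
        eps = 0.009 * contour.perimeter
        assert point_polygon_distance(pts, contour.vertices).max() <= eps + 1e-9

    def test_zigzag_collapses_to_farthest_pair(self):
        from orgquant.geometry import simplify_closed

        x = np.arange(40, dtype=float)
        y = 0.1 * (-1.0) ** np.arange(40)  # excursions far below eps
        pts = np.vstack([np.column_stack([x, y]), np.column_stack([x[::-1], y + 0.5])])
        eps = 2.0
        out = simplify_closed(pts, eps)
        ref = reference_rdp_closed(pts, eps)
        assert np.array_equal(out, ref)
        assert len(ref) == 2

    def test_matches_reference_on_random_chains(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            th = np.sort(rng.uniform(0, 2 * np.pi, n))
            r = rng.uniform(20, 60) * (1 + 0.2 * rng.standard_normal(n))
            pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
            eps = float(rng.uniform(0.5, 5.0))
            from orgquant.geometry import simplify_closed

            assert np.array_equal(simplify_closed(pts, eps), reference_rdp_closed(pts, eps))

    def test_vertices_subset_of_input(self, rng):
        m = random_blob_mask(rng)
        b = trace_boundary(CellCluster(1, m)).astype(float)
        contour = approximate_contour(b, 0.009)
        inset = {tuple(p) for p in b}
        assert all(tuple(v) in inset for v in contour.vertices)

    def test_degenerate_raises(self):
        tri = np.array([[0, 0], [10, 0.01], [20, 0]], float)
        with pytest.raises(DegenerateContourError):
            approximate_contour(tri, epsilon_rel=0.4)

    def test_bad_params(self):
        pts = np.array([[0, 0], [1, 0], [1, 1]], float)
        with pytest.raises(ParameterError):
            approximate_contour(pts, epsilon_rel=0.0)
        with pytest.raises(ParameterError):
            approximate_contour(pts[:2], 0.009)


# ------------------------------------------------------------ full chain


def test_segment_cells_two_disks():
    mask = make_disk_mask((80, 160), (40, 40), 22) | make_disk_mask(
        (80, 160), (120, 40), 30
    )
    img = IntensityImage(np.where(mask, 180.0, 10.0))
    res = segment_cells(image=img, erosion_radius=1, min_area=100)
    assert len(res.contours) == 2
    # sorted by area: the larger disk first
    assert res.clusters[0].area > res.clusters[1].area
    assert res.contours[0].source_label == 1
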