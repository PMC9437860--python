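"""Cell segmentation front-end.

Turns a raw cell-channel image (or a user-supplied binary mask) into per-cell
approximated boundary polygons through the chain: binarize -> erode ->
connected-component clustering -> hole patching / small-cluster removal ->
boundary tracing -> Douglas-Peucker contour approximation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.morphology import disk

from .errors import ClusterTooSmallError, DegenerateContourError, ParameterError
from .geometry import polygon_perimeter, simplify_closed
from .images import IntensityImage

#: Default relative Douglas-Peucker tolerance (fraction of contour perimeter).
DEFAULT_EPSILON_REL = 0.009


@dataclass
class CellCluster:
    """One connected foreground component, stored as a full-frame mask."""

    label: int
    mask: np.ndarray  # boolean, full image frame

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        """Set of (x, y) pixel coordinates belonging to the cluster."""
        rows, cols = np.nonzero(self.mask)
        return set(zip(cols.tolist(), rows.tolist()))


@dataclass
class CellContour:
    """Closed simplified polygon delimiting one cell.

    ``vertices`` are (x, y) points, a subset of the traced boundary pixels;
    the closing edge (last -> first) is implicit. ``perimeter`` is the arc
    length of the pre-approximation boundary chain.
    """

    vertices: np.ndarray
    source_label: int = 0
    perimeter: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("contour vertices must be (N, 2)")
        if len(self.vertices) < 3:
            raise DegenerateContourError(
                f"contour needs >= 3 vertices, got {len(self.vertices)}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def erode_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological erosion by a disk of the given radius.

    Pixels outside the image count as background, so the image border is
    eroded too. ``radius=0`` returns the mask unchanged.
    """
    if radius < 0:
        raise ParameterError(f"erosion radius must be >= 0, got {radius}")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return ndi.binary_erosion(mask, structure=disk(radius), border_value=0)


def binarize(
    image: IntensityImage,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold an intensity image; pixel true iff intensity > threshold.

    ``method='otsu'`` computes the threshold on the image; a constant image
    has no Otsu threshold, in which case a warning is issued and an all-false
    mask is returned. ``method='fixed'`` requires ``threshold``.
    """
    px = image.pixels
    if method == "fixed":
        if threshold is None:
            raise ParameterError("method='fixed' requires a threshold value")
        return px > threshold
    if method != "otsu":
        raise ParameterError(f"unknown threshold method {method!r}")
    if px.max() == px.min():
        warnings.warn(
            "constant image: Otsu threshold is degenerate, returning all-false",
            stacklevel=2,
        )
        return np.zeros_like(px, dtype=bool)
    from skimage.filters import threshold_otsu

    return px > threshold_otsu(px)


def label_clusters(mask: np.ndarray, connectivity: int = 8) -> list[CellCluster]:
    """Partition foreground pixels into connected components.

    Components are returned sorted by area descending (area ties broken by
    scan order) and relabeled 1..n in that order.
    """
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    n = int(lab.max())
    if n == 0:
        return []
    areas = np.bincount(lab.ravel())[1:]
    order = np.lexsort((np.arange(n), -areas))
    return [
        CellCluster(label=rank + 1, mask=lab == (orig + 1))
        for rank, orig in enumerate(order)
    ]


def clean_clusters(
    clusters: list[CellCluster], min_area: int = 500
) -> list[CellCluster]:
    """Patch interior holes and drop clusters smaller than ``min_area``.

    Survivors are re-sorted by post-fill area descending and relabeled 1..n.
    """
    if min_area < 0:
        raise ParameterError("min_area must be >= 0")
    filled = []
    for c in clusters:
        m = ndi.binary_fill_holes(c.mask)
        if int(m.sum()) >= min_area:
            filled.append(m)
    filled.sort(key=lambda m: -int(m.sum()))
    return [CellCluster(label=i + 1, mask=m) for i, m in enumerate(filled)]


# Moore neighborhood in clockwise screen order (row down): W, NW, N, NE, E, SE, S, SW
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_DIR_INDEX = {d: i for i, d in enumerate(_MOORE)}


def trace_boundary(cluster: CellCluster) -> np.ndarray:
    """Ordered closed outer boundary chain of a hole-free cluster.

    Returns (N, 2) integer (x, y) points, counter-clockwise in the
    mathematical (x right, y up) sense, each appearing once. The returned
    set equals the pixels with at least one false 4-neighbor.
    """
    mask = cluster.mask
    if cluster.area < 3:
        raise ClusterTooSmallError(f"cluster area {cluster.area} < 3")
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    h, w = mask.shape

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    # Moore-neighbor tracing with Jacob's stopping criterion. The backtrack
    # pixel is the background neighbor we entered the current pixel from;
    # west of the row-major-first pixel is background by construction.
    back = (start[0], start[1] - 1)
    cur = start
    chain = [start]
    visited = {(cur, back)}
    max_steps = 4 * mask.size + 8
    for _ in range(max_steps):
        db = _DIR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            d = (db + k) % 8
            dr, dc = _MOORE[d]
            cand = (cur[0] + dr, cur[1] + dc)
            if is_fg(*cand):
                nxt = cand
                pdr, pdc = _MOORE[(d - 1) % 8]
                back = (cur[0] + pdr, cur[1] + pdc)  # last background examined
                break
        if nxt is None:
            break  # isolated pixel (area >= 3 makes this unreachable)
        cur = nxt
        if ((cur, back)) in visited:
            break  # transition is deterministic: a repeated state closes the walk
        visited.add((cur, back))
        chain.append(cur)

    # keep only 4-boundary pixels, first occurrence order
    seen: set[tuple[int, int]] = set()
    pts: list[tuple[int, int]] = []
    for r, c in chain:
        if (r, c) in seen:
            continue
        if (
            not is_fg(r - 1, c)
            or not is_fg(r + 1, c)
            or not is_fg(r, c - 1)
            or not is_fg(r, c + 1)
        ):
            seen.add((r, c))
            pts.append((r, c))
    out = np.array([(c, r) for r, c in pts], dtype=np.int64)
    # orient counter-clockwise (positive shoelace area in x/y coordinates)
    x, y = out[:, 0].astype(float), out[:, 1].astype(float)
    area2 = float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    if area2 < 0:
        out = out[::-1].copy()
    return out


def approximate_contour(
    boundary: np.ndarray,
    epsilon_rel: float = DEFAULT_EPSILON_REL,
    source_label: int = 0,
) -> CellContour:
    """Douglas-Peucker simplification of a closed boundary chain.

    The absolute tolerance is ``epsilon_rel`` times the chain perimeter. The
    closed-curve recursion is seeded with the two mutually farthest boundary
    points. Raises :class:`DegenerateContourError` if fewer than 3 vertices
    survive.
    """
    pts = np.asarray(boundary, dtype=np.float64)
    if len(pts) < 3:
        raise ParameterError("boundary needs >= 3 points")
    if epsilon_rel <= 0:
        raise ParameterError("epsilon_rel must be > 0")
    perimeter = polygon_perimeter(pts, closed=True)
    eps = epsilon_rel * perimeter
    simplified = simplify_closed(pts, eps)
    if len(simplified) < 3:
        raise DegenerateContourError(
            f"contour collapsed to {len(simplified)} vertices at eps={eps:.3g}"
        )
    return CellContour(
        vertices=simplified, source_label=source_label, perimeter=perimeter
    )


@dataclass
class SegmentationResult:
    clusters: list[CellCluster] = field(default_factory=list)
    contours: list[CellContour] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def segment_cells(
    image: IntensityImage | None = None,
    mask: np.ndarray | None = None,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    erosion_radius: int = 3,
    connectivity: int = 8,
    min_area: int = 500,
    epsilon_rel: float = DEFAULT_EPSILON_REL,
) -> SegmentationResult:
    """Full pipeline: image/mask -> cleaned clusters + approximated contours."""
    if mask is None:
        if image is None:
            raise ParameterError("either an image or a mask is required")
        mask = binarize(image, method=threshold_method, threshold=threshold_value)
    mask = erode_mask(np.asarray(mask, dtype=bool), erosion_radius)
    clusters = clean_clusters(label_clusters(mask, connectivity), min_area)
    result = SegmentationResult(clusters=clusters)
    for c in clusters:
        try:
            chain = trace_boundary(c)
            result.contours.append(
                approximate_contour(chain, epsilon_rel, source_label=c.label)
            )
        except (DegenerateContourError, ClusterTooSmallError) as exc:
            result.warnings.append(f"cluster {c.label}: {exc}")
    return result
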