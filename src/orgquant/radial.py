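"""Cumulative radial intensity profiling.

Given a cell contour and an interior center point, a family of nested
polygons is built by scaling every contour vertex toward the center at
fractional distances d = 1/n, 2/n, ..., 1. Each in-cell pixel is assigned
to the innermost polygon containing it, per-shell intensities are summed,
and the running sum is normalized by the total in-cell intensity to give a
cumulative profile on [0, 1]. A left-shifted (higher) curve means signal
concentrated near the center; a right-shifted (lower) curve means a
peripheral distribution. The mean of the cumulative values (profile AUC)
is the scalar summary used for group testing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Point, Polygon
from shapely.ops import polylabel

from .errors import (
    CenterOutsideError,
    FrameMismatchError,
    InsufficientDataError,
    InvalidProfileError,
    ParameterError,
)
from .geometry import points_in_polygon
from .images import IntensityImage
from .segmentation import CellContour

logger = logging.getLogger(__name__)

DEFAULT_INCREMENTS = 10


@dataclass
class ShellGeometry:
    """Nested concentric polygons from a cell center to its periphery."""

    center: np.ndarray
    fractions: np.ndarray
    polygons: list[np.ndarray]
    warnings: list[str] = field(default_factory=list)


@dataclass
class RadialProfile:
    """Per-cell cumulative normalized intensity at each distance fraction."""

    cell_id: int
    fractions: np.ndarray
    shell_intensity: np.ndarray
    cumulative: np.ndarray
    valid: bool = True
    warnings: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    labels: list[str]
    fractions: np.ndarray
    mean_curves: dict[str, np.ndarray]
    aucs: dict[str, np.ndarray]
    test: str
    statistic: float
    p_value: float
    shift: str


def _polygon_of(contour: CellContour | np.ndarray) -> np.ndarray:
    if isinstance(contour, CellContour):
        return contour.vertices
    return np.asarray(contour, dtype=np.float64)


def select_center(
    contour: CellContour | np.ndarray,
    mode: str = "centroid",
    point: tuple[float, float] | None = None,
    nucleus_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Choose the cell center point used as the origin of the shells.

    ``manual`` uses the supplied point (must be strictly inside the contour).
    ``centroid`` uses the polygon centroid; if the centroid falls outside a
    non-convex contour, the pole of inaccessibility is used instead and the
    fallback is logged. ``nucleus`` uses the centroid of a nucleus mask with
    the same fallback.
    """
    verts = _polygon_of(contour)
    poly = Polygon(verts)
    if mode == "manual":
        if point is None:
            raise ParameterError("mode='manual' requires a point")
        p = np.asarray(point, dtype=np.float64)
        if not poly.contains(Point(p)):
            raise CenterOutsideError(f"manual center {tuple(p)} is outside the contour")
        return p
    if mode == "centroid":
        cand = np.array([poly.centroid.x, poly.centroid.y])
    elif mode == "nucleus":
        if nucleus_mask is None:
            raise ParameterError("mode='nucleus' requires a nucleus mask")
        rows, cols = np.nonzero(np.asarray(nucleus_mask, dtype=bool))
        if len(rows) == 0:
            raise InsufficientDataError("nucleus mask is empty")
        cand = np.array([cols.mean(), rows.mean()])
    else:
        raise ParameterError(f"unknown center mode {mode!r}")
    if poly.contains(Point(cand)):
        return cand
    fallback = polylabel(poly, tolerance=0.5)
    logger.warning(
        "center mode %r gave a point outside the contour; "
        "falling back to pole of inaccessibility",
        mode,
    )
    p = np.array([fallback.x, fallback.y])
    if not poly.contains(Point(p)):
        raise CenterOutsideError("could not find an interior center point")
    return p


def build_shells(
    contour: CellContour | np.ndarray,
    center: np.ndarray | tuple[float, float],
    n_increments: int = DEFAULT_INCREMENTS,
) -> ShellGeometry:
    """Scale the contour toward the center at fractions k/n, k = 1..n.

    Shell polygon vertex i at fraction d is ``center + d * (v_i - center)``;
    the outermost polygon (d = 1) is the contour itself. If an inner polygon
    is not contained in the contour (a non-star-convex shape seen from this
    center) the geometry is flagged with a warning rather than rejected.
    """
    verts = _polygon_of(contour)
    center = np.asarray(center, dtype=np.float64)
    if n_increments < 2:
        raise ParameterError("n_increments must be >= 2")
    poly = Polygon(verts)
    if not poly.contains(Point(center)):
        raise CenterOutsideError(f"center {tuple(center)} is not strictly inside")
    fractions = np.arange(1, n_increments + 1, dtype=np.float64) / n_increments
    polygons: list[np.ndarray] = []
    warns: list[str] = []
    for d in fractions:
        if d == 1.0:
            polygons.append(verts.copy())
        else:
            polygons.append(center + d * (verts - center))
    for d, p in zip(fractions[:-1], polygons[:-1]):
        inner = Polygon(p)
        if not inner.is_valid or not poly.covers(inner):
            warns.append(
                f"shell at d={d:g} is not nested inside the contour; "
                "contour is not star-convex about the chosen center"
            )
            logger.warning(warns[-1])
            break
    return ShellGeometry(
        center=center, fractions=fractions, polygons=polygons, warnings=warns
    )


def cumulative_profile(
    image: IntensityImage,
    shells: ShellGeometry,
    cell_mask: np.ndarray | None = None,
    cell_id: int = 0,
) -> RadialProfile:
    """Sum intensity per concentric shell and normalize cumulatively.

    Each pixel center inside the outermost polygon is assigned to the
    innermost polygon that contains it (even-odd rule). Pixels inside
    ``cell_mask`` but outside the outermost polygon (contour-approximation
    slack) are assigned to the outermost shell. A zero total intensity
    yields an invalid profile with an all-zero cumulative curve.
    """
    px = image.pixels
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != px.shape:
            raise FrameMismatchError(
                f"mask shape {cell_mask.shape} != image shape {px.shape}"
            )
    outer = shells.polygons[-1]
    xmin, xmax = outer[:, 0].min(), outer[:, 0].max()
    ymin, ymax = outer[:, 1].min(), outer[:, 1].max()
    if cell_mask is not None and cell_mask.any():
        mrows, mcols = np.nonzero(cell_mask)
        xmin, xmax = min(xmin, mcols.min()), max(xmax, mcols.max())
        ymin, ymax = min(ymin, mrows.min()), max(ymax, mrows.max())
    x0 = max(int(np.floor(xmin)), 0)
    x1 = min(int(np.ceil(xmax)), px.shape[1] - 1)
    y0 = max(int(np.floor(ymin)), 0)
    y1 = min(int(np.ceil(ymax)), px.shape[0] - 1)
    if x1 < x0 or y1 < y0:
        raise FrameMismatchError("contour does not overlap the image")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    vals = px[y0 : y1 + 1, x0 : x1 + 1].ravel()

    n = len(shells.fractions)
    inside_outer = points_in_polygon(pts, outer)
    assignment = np.full(len(pts), -1, dtype=np.int64)
    unassigned = inside_outer.copy()
    for k in range(n - 1):
        idx = np.nonzero(unassigned)[0]
        if len(idx) == 0:
            break
        hit = points_in_polygon(pts[idx], shells.polygons[k])
        assignment[idx[hit]] = k
        unassigned[idx[hit]] = False
    assignment[unassigned] = n - 1

    shell_intensity = np.zeros(n)
    for k in range(n):
        shell_intensity[k] = vals[assignment == k].sum()
    if cell_mask is not None:
        # slack pixels: inside the cleaned cluster but outside polygon(1.0)
        sub = cell_mask[y0 : y1 + 1, x0 : x1 + 1].ravel()
        slack = sub & ~inside_outer
        shell_intensity[-1] += vals[slack].sum()

    total = shell_intensity.sum()
    warns = list(shells.warnings)
    if total <= 0:
        warns.append("zero total in-cell intensity; profile invalid")
        return RadialProfile(
            cell_id=cell_id,
            fractions=shells.fractions.copy(),
            shell_intensity=shell_intensity,
            cumulative=np.zeros(n),
            valid=False,
            warnings=warns,
        )
    return RadialProfile(
        cell_id=cell_id,
        fractions=shells.fractions.copy(),
        shell_intensity=shell_intensity,
        cumulative=np.cumsum(shell_intensity) / total,
        valid=True,
        warnings=warns,
    )


def profile_auc(profile: RadialProfile) -> float:
    """Mean of the cumulative curve; higher = more perinuclear."""
    if not profile.valid:
        raise InvalidProfileError(
            f"cell {profile.cell_id}: AUC undefined for an invalid profile"
        )
    return float(np.mean(profile.cumulative))


def compare_groups(
    groups: dict[str, list[RadialProfile]],
    test: str = "auto",
) -> GroupComparison:
    """Compare cumulative profiles between groups via per-cell AUC.

    Two groups -> two-sided Welch t-test; more -> one-way ANOVA. Mean curves
    are computed over the valid profiles of each group on the shared
    fraction grid.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise InsufficientDataError("need at least 2 groups")
    valid = {
        lab: [p for p in profs if p.valid] for lab, profs in groups.items()
    }
    for lab, profs in valid.items():
        if len(profs) < 2:
            raise InsufficientDataError(
                f"group {lab!r} has {len(profs)} valid profiles; need >= 2"
            )
    grid = valid[labels[0]][0].fractions
    for lab, profs in valid.items():
        for p in profs:
            if len(p.fractions) != len(grid) or not np.allclose(p.fractions, grid):
                raise FrameMismatchError(
                    f"group {lab!r}: fraction grid mismatch for cell {p.cell_id}"
                )
    if test == "auto":
        test = "t_test" if len(labels) == 2 else "anova"
    if test == "t_test" and len(labels) != 2:
        raise ParameterError("t_test requires exactly 2 groups")
    if test not in ("t_test", "anova"):
        raise ParameterError(f"unknown test {test!r}")

    mean_curves = {
        lab: np.mean([p.cumulative for p in profs], axis=0)
        for lab, profs in valid.items()
    }
    aucs = {
        lab: np.array([profile_auc(p) for p in profs]) for lab, profs in valid.items()
    }
    if test == "t_test":
        res = stats.ttest_ind(aucs[labels[0]], aucs[labels[1]], equal_var=False)
        statistic, p_value = float(res.statistic), float(res.pvalue)
        diff = aucs[labels[0]].mean() - aucs[labels[1]].mean()
        if diff == 0:
            shift = "none"
        elif diff > 0:
            shift = f"peripheral in {labels[1]}"
        else:
            shift = f"peripheral in {labels[0]}"
    else:
        res = stats.f_oneway(*[aucs[lab] for lab in labels])
        statistic, p_value = float(res.statistic), float(res.pvalue)
        means = {lab: aucs[lab].mean() for lab in labels}
        if len(set(means.values())) == 1:
            shift = "none"
        else:
            shift = f"most peripheral in {min(means, key=means.get)}"
    return GroupComparison(
        labels=labels,
        fractions=grid.copy(),
        mean_curves=mean_curves,
        aucs=aucs,
        test=test,
        statistic=statistic,
        p_value=p_value,
        shift=shift,
    )
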