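"""Seeded synthetic fixtures with known ground truth.

Two generators:

* :func:`generate_cell` draws a star-convex cell body (smooth random radial
  function), fills a cytoplasmic "shape" channel, and plants Gaussian puncta
  in an "organelle" channel at normalized radii sampled from a Beta(a, b)
  law — Beta(1, 3)-like specs give perinuclear fixtures, Beta(3, 1)-like
  peripheral ones.
* :func:`generate_timelapse` renders populations of puncta moving at
  constant signed velocities along a path (anterograde +, retrograde -,
  stationary 0), laying the puncta out in disjoint swept intervals so that
  trajectories never cross.

All randomness flows from the spec's ``seed``; identical specs give
bit-identical arrays. Optional Poisson shot noise and Gaussian read noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .errors import ParameterError, SimulationSpecError
from .geometry import points_in_polygon
from .images import IntensityImage, TimeLapse
from .kymograph import PathSpec
from .segmentation import CellContour


@dataclass
class SyntheticCellSpec:
    image_size: tuple[int, int] = (192, 192)  # (height, width)
    mean_radius: float = 60.0
    roughness: float = 0.08
    n_lobes: int = 5
    center: tuple[float, float] | None = None  # (x, y); default image center
    n_puncta: int = 200
    beta_a: float = 1.0
    beta_b: float = 3.0
    punctum_amplitude: float = 100.0
    psf_sigma: float = 1.5
    background: float = 5.0
    cytoplasm_level: float = 40.0
    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    concave: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ParameterError("Beta parameters must be > 0")
        if self.n_puncta < 0:
            raise ParameterError("n_puncta must be >= 0")
        if self.mean_radius < 10:
            raise ParameterError("mean_radius must be >= 10 px")


@dataclass
class SyntheticMotionSpec:
    n_frames: int = 70
    dt: float = 1.0
    pixel_size: float = 1.0
    n_anterograde: int = 10
    n_retrograde: int = 10
    n_stationary: int = 10
    v_anterograde: float = 2.0  # px/frame, along increasing path coordinate
    v_retrograde: float = -2.0
    punctum_amplitude: float = 80.0
    psf_sigma: float = 1.5
    background: float = 10.0
    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    margin: float = 8.0  # gap between swept intervals, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.v_anterograde <= 0:
            raise ParameterError("v_anterograde must be > 0")
        if self.v_retrograde >= 0:
            raise ParameterError("v_retrograde must be < 0")


@dataclass
class CellGroundTruth:
    """One record per planted punctum."""

    radii: np.ndarray  # normalized radius in [0, 1]
    angles: np.ndarray
    positions: np.ndarray  # (n, 2) image (x, y)


@dataclass
class MotionGroundTruth:
    labels: list[str]  # anterograde / retrograde / stationary per punctum
    start_positions: np.ndarray  # path coordinate at frame 0
    velocities: np.ndarray  # px/frame, signed
    trajectories: np.ndarray  # (n_puncta, n_frames) path coordinates
    warnings: list[str] = field(default_factory=list)


def _radial_boundary(spec: SyntheticCellSpec, rng: np.random.Generator):
    """Random smooth positive radial function r(theta) and its contour."""
    amps = rng.normal(0.0, 1.0, spec.n_lobes)
    phases = rng.uniform(0.0, 2 * np.pi, spec.n_lobes)
    ks = np.arange(2, spec.n_lobes + 2)

    def r_of(theta: np.ndarray) -> np.ndarray:
        mod = np.zeros_like(theta)
        for a, ph, k in zip(amps, phases, ks):
            mod += (a / k) * np.cos(k * theta + ph)
        r = spec.mean_radius * (1.0 + spec.roughness * mod)
        return np.clip(r, 0.3 * spec.mean_radius, 1.9 * spec.mean_radius)

    return r_of


def _add_gaussian_spots(
    img: np.ndarray, positions: np.ndarray, amplitude: float, sigma: float
) -> None:
    """Additively render symmetric Gaussian spots (in place)."""
    h, w = img.shape
    half = max(int(np.ceil(4 * sigma)), 2)
    for px, py in np.atleast_2d(positions):
        x0 = max(int(np.floor(px)) - half, 0)
        x1 = min(int(np.ceil(px)) + half + 1, w)
        y0 = max(int(np.floor(py)) - half, 0)
        y1 = min(int(np.ceil(py)) + half + 1, h)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((xx - px) ** 2 + (yy - py) ** 2) / (2 * sigma**2)
        )


def _apply_noise(
    img: np.ndarray, rng: np.random.Generator, shot: bool, read_sigma: float
) -> np.ndarray:
    if shot:
        img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
    if read_sigma > 0:
        img = img + rng.normal(0.0, read_sigma, img.shape)
    return np.maximum(img, 0.0)


def generate_cell(
    spec: SyntheticCellSpec,
) -> tuple[IntensityImage, IntensityImage, CellContour, CellGroundTruth]:
    """Render one synthetic cell: organelle channel, shape channel, contour, truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    center = (
        np.array(spec.center, dtype=np.float64)
        if spec.center is not None
        else np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    )

    if spec.concave:
        # crescent: disk minus an offset disk; non-star-convex about most centers
        body = Point(center).buffer(spec.mean_radius, quad_segs=45)
        bite = Point(center + np.array([0.9 * spec.mean_radius, 0.0])).buffer(
            0.8 * spec.mean_radius, quad_segs=45
        )
        shape = body.difference(bite)
        verts = np.asarray(shape.exterior.coords)[:-1]
        poly = Polygon(verts)

        def boundary_dist(theta: np.ndarray) -> np.ndarray:
            far = 3 * spec.mean_radius
            out = np.zeros_like(theta)
            for i, th in enumerate(theta):
                ray = LineString(
                    [center, center + far * np.array([np.cos(th), np.sin(th)])]
                )
                hit = ray.intersection(poly.exterior)
                if hit.is_empty:
                    out[i] = 0.0
                else:
                    out[i] = min(
                        Point(center).distance(g)
                        for g in getattr(hit, "geoms", [hit])
                    )
            return out

    else:
        r_of = _radial_boundary(spec, rng)
        thetas = np.linspace(0.0, 2 * np.pi, 181)[:-1]
        rr = r_of(thetas)
        verts = center + np.column_stack([rr * np.cos(thetas), rr * np.sin(thetas)])
        poly = Polygon(verts)
        boundary_dist = r_of

    contour = CellContour(vertices=verts, source_label=1)
    if not poly.contains(Point(center)):
        raise SimulationSpecError("generated shape does not contain its center")

    # shape channel: uniform cytoplasm inside the polygon
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    inside = points_in_polygon(pts, verts).reshape(h, w)
    shape_img = np.full((h, w), spec.background, dtype=np.float64)
    shape_img[inside] += spec.cytoplasm_level

    # organelle channel: puncta at Beta-distributed normalized radii
    radii = rng.beta(spec.beta_a, spec.beta_b, spec.n_puncta)
    angles = rng.uniform(0.0, 2 * np.pi, spec.n_puncta)
    dists = boundary_dist(angles)
    positions = center + (radii * dists)[:, None] * np.column_stack(
        [np.cos(angles), np.sin(angles)]
    )
    org_img = np.full((h, w), spec.background, dtype=np.float64)
    if spec.n_puncta:
        _add_gaussian_spots(
            org_img, positions, spec.punctum_amplitude, spec.psf_sigma
        )

    org_img = _apply_noise(org_img, rng, spec.shot_noise, spec.read_noise_sigma)
    shape_img = _apply_noise(shape_img, rng, spec.shot_noise, spec.read_noise_sigma)
    truth = CellGroundTruth(radii=radii, angles=angles, positions=positions)
    return (
        IntensityImage(org_img),
        IntensityImage(shape_img),
        contour,
        truth,
    )


def _layout_puncta(
    spec: SyntheticMotionSpec, path_length: float, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Assign non-overlapping swept intervals along the path.

    Each punctum owns [start, start + v*(n_frames-1)] (or a point interval
    for stationary puncta) plus a margin; population order is shuffled so
    directions are interleaved along the path.
    """
    steps = spec.n_frames - 1
    entries: list[tuple[str, float]] = (
        [("anterograde", spec.v_anterograde)] * spec.n_anterograde
        + [("retrograde", spec.v_retrograde)] * spec.n_retrograde
        + [("stationary", 0.0)] * spec.n_stationary
    )
    if not entries:
        raise ParameterError("no puncta requested")
    order = rng.permutation(len(entries))
    labels: list[str] = []
    velocities = np.empty(len(entries))
    starts = np.empty(len(entries))
    cursor = spec.margin
    for rank, idx in enumerate(order.tolist()):
        label, v = entries[idx]
        sweep = abs(v) * steps
        if cursor + sweep + spec.margin > path_length:
            raise SimulationSpecError(
                f"punctum {rank} ({label}) does not fit: needs "
                f"{cursor + sweep + spec.margin:.1f} px of path, "
                f"path has {path_length:.1f}"
            )
        start = cursor if v >= 0 else cursor + sweep
        labels.append(label)
        velocities[rank] = v
        starts[rank] = start
        cursor += sweep + spec.margin
    return labels, starts, velocities


def generate_timelapse(
    spec: SyntheticMotionSpec,
    path: PathSpec,
    frame_shape: tuple[int, int] | None = None,
) -> tuple[TimeLapse, MotionGroundTruth]:
    """Render constant-velocity puncta moving along a path."""
    rng = np.random.default_rng(spec.seed)
    labels, starts, velocities = _layout_puncta(spec, path.length, rng)
    steps = np.arange(spec.n_frames, dtype=np.float64)
    traj = starts[:, None] + velocities[:, None] * steps[None, :]
    if traj.min() < 0 or traj.max() > path.length:
        bad = int(np.argmax(np.any((traj < 0) | (traj > path.length), axis=1)))
        raise SimulationSpecError(f"punctum {bad} exits the path")

    if frame_shape is None:
        pad = 15
        xs, ys = path.vertices[:, 0], path.vertices[:, 1]
        frame_shape = (
            int(np.ceil(ys.max())) + pad + 1,
            int(np.ceil(xs.max())) + pad + 1,
        )
    h, w = frame_shape

    frames = []
    for t in range(spec.n_frames):
        img = np.full((h, w), spec.background, dtype=np.float64)
        pts, _ = path.sample(traj[:, t])
        _add_gaussian_spots(img, pts, spec.punctum_amplitude, spec.psf_sigma)
        img = _apply_noise(img, rng, spec.shot_noise, spec.read_noise_sigma)
        frames.append(IntensityImage(img, pixel_size=spec.pixel_size))

    stack = TimeLapse(frames=frames, dt=spec.dt, pixel_size=spec.pixel_size)
    truth = MotionGroundTruth(
        labels=labels,
        start_positions=starts,
        velocities=velocities,
        trajectories=traj,
    )
    return stack, truth


CELL_PRESETS = {
    "perinuclear": dict(beta_a=1.0, beta_b=3.0),
    "peripheral": dict(beta_a=3.0, beta_b=1.0),
    "uniform": dict(beta_a=1.0, beta_b=1.0),
}


def generate_cohort(
    preset: str,
    n_cells: int,
    seed: int,
    **overrides,
) -> list[tuple[IntensityImage, IntensityImage, CellContour, CellGroundTruth]]:
    """Generate ``n_cells`` cells for a named radial-placement preset."""
    if preset not in CELL_PRESETS:
        raise ParameterError(
            f"unknown preset {preset!r}; choose from {sorted(CELL_PRESETS)}"
        )
    params = dict(CELL_PRESETS[preset])
    params.update(overrides)
    root = np.random.SeedSequence(seed)
    cells = []
    for child in root.spawn(n_cells):
        cell_seed = int(child.generate_state(1)[0])
        cells.append(generate_cell(SyntheticCellSpec(seed=cell_seed, **params)))
    return cells
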