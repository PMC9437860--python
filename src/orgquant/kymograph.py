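"""Kymograph construction and transport-event counting.

A kymograph is a position x time intensity matrix sampled along a segmented
line drawn over a time lapse. The path is resampled at unit arc-length
spacing; at each sample the intensity is the maximum over a small window
perpendicular to the path (bilinear interpolation at subpixel coordinates).
Tracks are classified by net displacement along the path coordinate:
anterograde (increasing, proximal -> distal), retrograde (decreasing), or
stationary (below threshold).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    DataError,
    InsufficientDataError,
    ParameterError,
    PathBoundsError,
    TrackTooShortError,
)
from .images import TimeLapse

DEFAULT_PATH_WIDTH = 3
DEFAULT_STATIONARY_PX = 2.0


@dataclass
class PathSpec:
    """Segmented line along which a kymograph is read.

    Vertex order defines orientation: the first vertex is proximal, so
    increasing path coordinate is the anterograde direction.
    """

    vertices: np.ndarray
    width: int = DEFAULT_PATH_WIDTH

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("path vertices must be (N, 2)")
        if len(self.vertices) < 2:
            raise ParameterError("a path needs at least 2 vertices")
        if self.length <= 0:
            raise ParameterError("path must have positive arc length")
        if self.width < 1:
            raise ParameterError("path width must be >= 1")

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum()
        )

    def reversed(self) -> "PathSpec":
        return PathSpec(vertices=self.vertices[::-1].copy(), width=self.width)

    def sample(self, arclengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) points and unit tangents at the given arc-length positions."""
        seg = np.diff(self.vertices, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = np.clip(np.asarray(arclengths, dtype=np.float64), 0.0, cum[-1])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        t = (s - cum[idx]) / seglen[idx]
        pts = self.vertices[idx] + t[:, None] * seg[idx]
        tangents = seg[idx] / seglen[idx, None]
        return pts, tangents


@dataclass
class Kymograph:
    """Intensity matrix: rows = path positions (unit px spacing), cols = frames."""

    matrix: np.ndarray
    path_length: float
    dt: float
    pixel_size: float

    @property
    def n_positions(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.matrix.shape[1])


@dataclass
class Track:
    """Time-ordered point sequence, either 1D (path coordinate) or 2D (x, y)."""

    track_id: int
    frames: np.ndarray
    positions: np.ndarray  # (N,) path positions or (N, 2) image points
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if len(self.frames) != len(self.positions):
            raise ParameterError("frames and positions length mismatch")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ParameterError("frame indices must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def net_displacement(self) -> float:
        """Signed for 1D path tracks; Euclidean norm for 2D tracks."""
        if self.n_points < 2:
            return 0.0
        if self.positions.ndim == 1:
            return float(self.positions[-1] - self.positions[0])
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))


@dataclass
class TransportEventCounts:
    anterograde: int = 0
    retrograde: int = 0
    stationary: int = 0
    compartment: str = "none"

    @property
    def total(self) -> int:
        return self.anterograde + self.retrograde + self.stationary


class TrackStats(NamedTuple):
    duration_s: float
    displacement_um: float
    speed_um_per_s: float


def build_kymograph(stack: TimeLapse, path: PathSpec) -> Kymograph:
    """Sample the stack along the path: rows round(L)+1, one column per frame.

    Intensity at each (position, frame) is the maximum over ``path.width``
    samples taken perpendicular to the local tangent, each read by bilinear
    interpolation.
    """
    h, w = stack.frame_shape
    n_rows = int(round(path.length)) + 1
    s = np.arange(n_rows, dtype=np.float64)
    pts, tangents = path.sample(s)
    if (
        pts[:, 0].min() < 0
        or pts[:, 0].max() > w - 1
        or pts[:, 1].min() < 0
        or pts[:, 1].max() > h - 1
    ):
        raise PathBoundsError("path exits image bounds")
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    offsets = np.arange(path.width, dtype=np.float64) - (path.width - 1) / 2.0
    # sample coordinates: (n_offsets, n_rows, 2)
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    matrix = np.empty((n_rows, stack.n_frames))
    yx = np.stack([coords[..., 1], coords[..., 0]], axis=0).reshape(2, -1)
    for t, frame in enumerate(stack.frames):
        vals = ndi.map_coordinates(
            frame.pixels, yx, order=1, mode="nearest"
        ).reshape(path.width, n_rows)
        matrix[:, t] = vals.max(axis=0)
    return Kymograph(
        matrix=matrix,
        path_length=path.length,
        dt=stack.dt,
        pixel_size=stack.pixel_size,
    )


def classify_track(
    track: Track, stationary_threshold: float = DEFAULT_STATIONARY_PX
) -> str:
    """Label a path track anterograde / retrograde / stationary.

    Net displacement below the threshold (in pixels) is stationary;
    otherwise the sign decides: positive (toward distal) is anterograde.
    """
    if track.n_points < 2:
        raise TrackTooShortError(
            f"track {track.track_id} has {track.n_points} point(s); need >= 2"
        )
    if track.positions.ndim != 1:
        raise ParameterError("classification needs 1D path-coordinate tracks")
    disp = track.net_displacement
    if abs(disp) < stationary_threshold:
        return "stationary"
    return "anterograde" if disp > 0 else "retrograde"


def count_events(
    tracks: list[Track],
    stationary_threshold: float = DEFAULT_STATIONARY_PX,
    compartment: str = "none",
) -> TransportEventCounts:
    """Tally classify_track over all tracks (one classified track = one event)."""
    counts = TransportEventCounts(compartment=compartment)
    for i, tr in enumerate(tracks):
        try:
            label = classify_track(tr, stationary_threshold)
        except TrackTooShortError as exc:
            raise TrackTooShortError(f"track index {i}: {exc}") from exc
        if label == "anterograde":
            counts.anterograde += 1
        elif label == "retrograde":
            counts.retrograde += 1
        else:
            counts.stationary += 1
    return counts


def classify_processes(lengths: list[float]) -> list[str]:
    """Label each neuronal process axon or dendrite by relative length.

    A process is an axon iff its length is at least 3x the median length of
    the other processes.
    """
    if len(lengths) < 2:
        raise InsufficientDataError("need at least 2 processes to classify")
    arr = np.asarray(lengths, dtype=np.float64)
    labels = []
    for i in range(len(arr)):
        others = np.delete(arr, i)
        labels.append("axon" if arr[i] >= 3.0 * np.median(others) else "dendrite")
    return labels


def track_stats(track: Track, dt: float, pixel_size: float) -> TrackStats:
    """Duration (s), net displacement (um, signed for path tracks), speed (um/s)."""
    if track.n_points < 2:
        raise TrackTooShortError(
            f"track {track.track_id} has {track.n_points} point(s); need >= 2"
        )
    duration = float(track.frames[-1] - track.frames[0]) * dt
    if duration <= 0:
        raise DataError(f"track {track.track_id} has zero duration")
    displacement = track.net_displacement * pixel_size
    return TrackStats(
        duration_s=duration,
        displacement_um=displacement,
        speed_um_per_s=abs(displacement) / duration,
    )


def detect_kymo_peaks(
    kymo: Kymograph,
    threshold: float,
    smooth_sigma: float = 1.0,
) -> list[list[tuple[float, float]]]:
    """Per-frame 1D peak detection on kymograph columns.

    Returns, per frame, a list of (position, intensity) with center-of-mass
    subpixel refinement over a 3-sample window.
    """
    out: list[list[tuple[float, float]]] = []
    for t in range(kymo.n_frames):
        col = kymo.matrix[:, t]
        sm = ndi.gaussian_filter1d(col, smooth_sigma) if smooth_sigma > 0 else col
        peaks: list[tuple[float, float]] = []
        for p in range(1, len(sm) - 1):
            if sm[p] > threshold and sm[p] >= sm[p - 1] and sm[p] > sm[p + 1]:
                w = np.maximum(sm[p - 1 : p + 2], 0.0)
                tot = w.sum()
                dp = 0.0 if tot == 0 else float((w[2] - w[0]) / tot)
                peaks.append((p + dp, float(col[p])))
        out.append(peaks)
    return out


def extract_tracks(
    kymo: Kymograph,
    threshold: float,
    max_disp: float = 5.0,
    min_length: int = 3,
    smooth_sigma: float = 1.0,
) -> list[Track]:
    """Detect peaks per kymograph column and link them into path tracks."""
    from .tracking import SpotDetection, link_spots

    detections: list[list[SpotDetection]] = []
    for t, peaks in enumerate(detect_kymo_peaks(kymo, threshold, smooth_sigma)):
        detections.append(
            [SpotDetection(frame_index=t, x=pos, y=0.0, intensity=val)
             for pos, val in peaks]
        )
    tracks2d = link_spots(detections, max_disp=max_disp)
    out = []
    for tr in tracks2d:
        if tr.n_points < min_length:
            continue
        out.append(
            Track(
                track_id=len(out) + 1,
                frames=tr.frames,
                positions=tr.positions[:, 0],
                intensities=tr.intensities,
            )
        )
    return out
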