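"""Minimal spot detection and frame-to-frame linking.

Detection: difference-of-Gaussians response, 3x3 local maxima above a
threshold, center-of-mass subpixel refinement. Linking: greedy nearest
neighbor per consecutive frame pair, candidate pairs taken in ascending
distance order (ties by lower spot indices), links beyond ``max_disp``
rejected. No gap closing: a missed detection terminates a track.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .images import IntensityImage, TimeLapse
from .kymograph import Track

MIN_TRACK_LENGTH = 3


@dataclass
class SpotDetection:
    frame_index: int
    x: float
    y: float
    intensity: float


def detect_spots(
    image: IntensityImage,
    sigma_small: float,
    sigma_large: float,
    threshold: float,
) -> list[SpotDetection]:
    """Difference-of-Gaussians local maxima with subpixel refinement.

    A pixel is a detection when the DoG response is a strict 3x3 local
    maximum (ties broken toward the first in scan order) above ``threshold``.
    Subpixel position is the center of mass of the nonnegative response in
    the 3x3 window around the peak.
    """
    if sigma_small <= 0 or sigma_large <= 0 or sigma_small >= sigma_large:
        raise ParameterError(
            f"need 0 < sigma_small < sigma_large, got {sigma_small}, {sigma_large}"
        )
    px = image.pixels
    dog = ndi.gaussian_filter(px, sigma_small) - ndi.gaussian_filter(px, sigma_large)
    footmax = ndi.maximum_filter(dog, size=3, mode="nearest")
    is_peak = (dog >= footmax) & (dog > threshold)
    # suppress plateau duplicates: keep the first pixel of each tied plateau
    rows, cols = np.nonzero(is_peak)
    detections: list[SpotDetection] = []
    taken = np.zeros_like(is_peak)
    h, w = dog.shape
    for r, c in zip(rows.tolist(), cols.tolist()):
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        if taken[r0:r1, c0:c1].any():
            continue
        taken[r, c] = True
        win = np.maximum(dog[r0:r1, c0:c1], 0.0)
        tot = win.sum()
        if tot > 0:
            yy, xx = np.mgrid[r0:r1, c0:c1]
            cy = float((win * yy).sum() / tot)
            cx = float((win * xx).sum() / tot)
        else:
            cy, cx = float(r), float(c)
        detections.append(
            SpotDetection(frame_index=0, x=cx, y=cy, intensity=float(px[r, c]))
        )
    return detections


def detect_spots_stack(
    stack: TimeLapse,
    sigma_small: float,
    sigma_large: float,
    threshold: float,
) -> list[list[SpotDetection]]:
    """Run :func:`detect_spots` on every frame, filling in frame indices."""
    out = []
    for t, frame in enumerate(stack.frames):
        dets = detect_spots(frame, sigma_small, sigma_large, threshold)
        for d in dets:
            d.frame_index = t
        out.append(dets)
    return out


def link_spots(
    detections: list[list[SpotDetection]], max_disp: float
) -> list[Track]:
    """Greedy nearest-neighbor linking across consecutive frames.

    For each frame pair, candidate links are sorted by ascending distance
    (ties by lower source then target index) and accepted greedily while
    both endpoints are free and the distance is within ``max_disp``.
    Unlinked detections start new tracks.
    """
    if max_disp <= 0:
        raise ParameterError("max_disp must be > 0")
    n_frames = len(detections)
    # successor[(t, i)] = index of linked spot in frame t+1
    successor: dict[tuple[int, int], int] = {}
    has_predecessor: set[tuple[int, int]] = set()
    for t in range(n_frames - 1):
        a = detections[t]
        b = detections[t + 1]
        if not a or not b:
            continue
        pa = np.array([[s.x, s.y] for s in a])
        pb = np.array([[s.x, s.y] for s in b])
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        ii, jj = np.nonzero(d <= max_disp)
        order = np.lexsort((jj, ii, d[ii, jj]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            successor[(t, i)] = j
            has_predecessor.add((t + 1, j))

    tracks: list[Track] = []
    for t in range(n_frames):
        for i, det in enumerate(detections[t]):
            if (t, i) in has_predecessor:
                continue
            frames = [t]
            points = [(det.x, det.y)]
            intens = [det.intensity]
            ct, ci = t, i
            while (ct, ci) in successor:
                ci = successor[(ct, ci)]
                ct += 1
                nxt = detections[ct][ci]
                frames.append(ct)
                points.append((nxt.x, nxt.y))
                intens.append(nxt.intensity)
            tracks.append(
                Track(
                    track_id=len(tracks) + 1,
                    frames=np.array(frames),
                    positions=np.array(points),
                    intensities=np.array(intens),
                )
            )
    return tracks


def track_stack(
    stack: TimeLapse,
    sigma_small: float,
    sigma_large: float,
    threshold: float,
    max_disp: float,
    min_length: int = MIN_TRACK_LENGTH,
) -> list[Track]:
    """Detect + link over a whole stack, dropping sub-minimum-length tracks."""
    detections = detect_spots_stack(stack, sigma_small, sigma_large, threshold)
    tracks = link_spots(detections, max_disp)
    kept = [t for t in tracks if t.n_points >= min_length]
    for i, t in enumerate(kept):
        t.track_id = i + 1
    return kept
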