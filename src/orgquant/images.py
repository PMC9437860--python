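"""Core image containers shared across modules.

Coordinate convention (used everywhere in this package): 0-based,
``x`` = column, ``y`` = row, pixel centers at integer coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass
class IntensityImage:
    """A 2D grid of nonnegative intensities with an optional physical scale.

    Parameters
    ----------
    pixels
        2D array of intensities, any real dtype, all values >= 0.
    pixel_size
        Physical size of one pixel in micrometres (default 1.0).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError(f"image must be 2D, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ParameterError("image must have at least one pixel")
        if np.any(self.pixels < 0):
            raise ParameterError("intensity values must be nonnegative")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class TimeLapse:
    """An ordered stack of equally shaped frames.

    ``dt`` is seconds per frame, ``pixel_size`` micrometres per pixel.
    """

    frames: list[IntensityImage] = field(default_factory=list)
    dt: float = 1.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ParameterError("a time lapse needs at least 2 frames")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        shape0 = self.frames[0].pixels.shape
        for i, f in enumerate(self.frames):
            if f.pixels.shape != shape0:
                raise ParameterError(
                    f"frame {i} shape {f.pixels.shape} != frame 0 shape {shape0}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].pixels.shape  # type: ignore[return-value]

    def as_array(self) -> np.ndarray:
        """Stack frames into a (T, H, W) float array."""
        return np.stack([f.pixels for f in self.frames], axis=0)
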