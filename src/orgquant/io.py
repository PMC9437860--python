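"""Readers and writers for images, paths, tracks, and result tables."""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import (
    ChannelRequiredError,
    FormatError,
    OutputCollisionError,
    ParameterError,
)
from .images import IntensityImage, TimeLapse
from .kymograph import PathSpec, Track
from .radial import RadialProfile

_ALLOWED_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")


def _load_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    else:
        raise FormatError(f"unsupported image format: {path.suffix}")
    if arr.dtype.name not in _ALLOWED_DTYPES and arr.dtype != bool:
        raise FormatError(f"{path}: unsupported bit depth {arr.dtype}")
    return arr


def read_image(
    path: str | Path,
    channel: int | None = None,
    pages_are_channels: bool = False,
    dt: float = 1.0,
    pixel_size: float = 1.0,
) -> IntensityImage | TimeLapse:
    """Read a TIFF/PNG as an IntensityImage or (multi-page) TimeLapse.

    3D arrays with a trailing axis of size 3/4 are treated as channels-last
    (RGB-like) and require ``channel``; other 3D arrays are a time series
    unless ``pages_are_channels``.
    """
    arr = _load_array(path)
    if arr.ndim == 2:
        return IntensityImage(arr.astype(np.float64), pixel_size=pixel_size)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and arr.shape[2] < min(arr.shape[:2]):
            if channel is None:
                raise ChannelRequiredError(
                    f"{path}: multi-channel image; pass a channel index"
                )
            if channel >= arr.shape[2]:
                raise FormatError(
                    f"{path}: channel {channel} out of range (has {arr.shape[2]})"
                )
            return IntensityImage(
                arr[:, :, channel].astype(np.float64), pixel_size=pixel_size
            )
        if pages_are_channels:
            if channel is None:
                raise ChannelRequiredError(
                    f"{path}: pages are channels; pass a channel index"
                )
            if channel >= arr.shape[0]:
                raise FormatError(
                    f"{path}: channel page {channel} out of range "
                    f"(has {arr.shape[0]})"
                )
            return IntensityImage(
                arr[channel].astype(np.float64), pixel_size=pixel_size
            )
        frames = [
            IntensityImage(arr[t].astype(np.float64), pixel_size=pixel_size)
            for t in range(arr.shape[0])
        ]
        return TimeLapse(frames=frames, dt=dt, pixel_size=pixel_size)
    raise FormatError(f"{path}: unsupported dimensionality {arr.ndim}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask image (nonzero = foreground)."""
    return _load_array(path) > 0


def read_csv(path: str | Path) -> pd.DataFrame:
    """CSV reader with exact (round-trip) float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def read_path_csv(path: str | Path, width: int = 3) -> PathSpec:
    """Read ordered path vertices from a CSV with columns x, y."""
    df = read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: path CSV needs columns 'x' and 'y'")
    return PathSpec(vertices=df[["x", "y"]].to_numpy(float), width=width)


def read_tracks_csv(path: str | Path) -> list[Track]:
    """Read 1D path tracks from a CSV with columns track_id, frame, position."""
    df = read_csv(path)
    for col in ("track_id", "frame", "position"):
        if col not in df.columns:
            raise FormatError(
                f"{path}: tracks CSV needs columns track_id, frame, position"
            )
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(np.int64),
                positions=grp["position"].to_numpy(float),
            )
        )
    return tracks


def profiles_to_frame(profiles: list[RadialProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for f, si, cum in zip(p.fractions, p.shell_intensity, p.cumulative):
            rows.append(
                dict(
                    cell_id=p.cell_id,
                    fraction=float(f),
                    shell_intensity=float(si),
                    cumulative=float(cum),
                    valid=bool(p.valid),
                )
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "fraction", "shell_intensity", "cumulative", "valid"]
    )


def frame_to_profiles(df: pd.DataFrame) -> list[RadialProfile]:
    profiles = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("fraction")
        profiles.append(
            RadialProfile(
                cell_id=int(cid),
                fractions=grp["fraction"].to_numpy(float),
                shell_intensity=grp["shell_intensity"].to_numpy(float),
                cumulative=grp["cumulative"].to_numpy(float),
                valid=bool(grp["valid"].iloc[0]),
            )
        )
    return profiles


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for i in range(t.n_points):
            row = dict(track_id=t.track_id, frame=int(t.frames[i]))
            if t.positions.ndim == 1:
                row["position"] = float(t.positions[i])
            else:
                row["x"] = float(t.positions[i, 0])
                row["y"] = float(t.positions[i, 1])
            if t.intensities is not None:
                row["intensity"] = float(t.intensities[i])
            rows.append(row)
    return pd.DataFrame(rows)


def contours_to_frame(contours) -> pd.DataFrame:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append(
                dict(cell_label=c.source_label, vertex_index=i, x=float(x), y=float(y))
            )
    return pd.DataFrame(rows, columns=["cell_label", "vertex_index", "x", "y"])


def write_results(
    objects: dict[str, pd.DataFrame],
    out_dir: str | Path,
    overwrite: bool = False,
    config=None,
    seed: int | None = None,
    warnings_list: list[str] | None = None,
) -> dict:
    """Write named DataFrames as CSVs plus a provenance manifest.

    Refuses to overwrite existing files unless ``overwrite``; returns the
    manifest dict (also written as ``manifest.json``). Reruns with the same
    inputs produce byte-identical files (no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [f"{name}.csv" for name in objects] + ["manifest.json"]
    if not overwrite:
        clashes = [n for n in names if (out_dir / n).exists()]
        if clashes:
            raise OutputCollisionError(
                f"refusing to overwrite existing files in {out_dir}: {clashes}"
            )
    written = []
    for name, df in objects.items():
        if not isinstance(df, pd.DataFrame):
            raise ParameterError(f"object {name!r} is not a DataFrame")
        target = out_dir / f"{name}.csv"
        # shortest round-trip float repr: full precision on re-read
        df.to_csv(
            target,
            index=False,
            lineterminator="\n",
            float_format=lambda v: repr(float(v)),
        )
        written.append(target.name)
    if not written:
        warnings.warn("empty result set: writing manifest only", stacklevel=2)
    manifest = {
        "files": written,
        "package_version": __version__,
        "config_hash": config.digest() if config is not None else None,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "warnings": warnings_list or [],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_labeled_mask(clusters, shape: tuple[int, int], path: str | Path) -> None:
    """Write cleaned clusters as a uint16 labeled TIFF."""
    lab = np.zeros(shape, dtype=np.uint16)
    for c in clusters:
        lab[c.mask] = c.label
    tifffile.imwrite(path, lab)


def write_kymograph(kymo, path: str | Path) -> None:
    tifffile.imwrite(path, kymo.matrix.astype(np.float32))
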