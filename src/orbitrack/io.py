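"""Tabular trajectory files and TIFF movie I/O.

Trajectory tables are plain CSV with a commented header that records units,
the coordinate convention (sample-fixed nm, x = axon axis, anterograde =
+x), and run provenance (seed, config hash).  The reader accepts a column
mapping so externally deposited trajectory files with different column
names/units can be ingested into the same standard frame.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .widefield import ImageStack

__all__ = [
    "STANDARD_COLUMNS",
    "write_trajectory",
    "read_trajectory",
    "write_movie",
    "read_movie",
]

STANDARD_COLUMNS = ["t_s", "x_nm", "y_nm", "z_nm", "counts", "tracked", "recenter_axis", "state"]

_CONVENTION = "sample-fixed nm; x = axon axis; anterograde = +x; 0-based sample index"


def write_trajectory(path, frame: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a trajectory table as CSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"convention": _CONVENTION, **(metadata or {})}
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def read_trajectory(path, column_map: dict | None = None, scale: dict | None = None):
    """Read a trajectory table; returns ``(frame, metadata)``.

    ``column_map`` renames source columns to the standard names (e.g.
    ``{"time": "t_s", "x": "x_nm"}``); ``scale`` multiplies named standard
    columns after renaming (e.g. ``{"x_nm": 1000.0}`` for µm sources).
    """
    path = Path(path)
    metadata: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    if column_map:
        frame = frame.rename(columns=column_map)
    for col, factor in (scale or {}).items():
        frame[col] = frame[col] * factor
    missing = {"t_s", "x_nm", "y_nm"} - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory table lacks required columns: {sorted(missing)}")
    if frame["t_s"].diff().iloc[1:].le(0).any():
        raise ValueError("t_s must be strictly increasing")
    return frame, metadata


def write_movie(path, stack: ImageStack) -> None:
    """Write a movie as a multi-page TIFF with timing/geometry metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "frame_interval_s": stack.frame_interval,
        "pixel_size_nm": stack.pixel_size,
        "recenter_frames": list(map(int, stack.recenter_frames)),
        "origins_nm": np.asarray(stack.origins).tolist(),
    }
    tifffile.imwrite(path, stack.frames.astype(np.float32), metadata=meta)


def read_movie(path) -> ImageStack:
    """Read a multi-page TIFF movie written by :func:`write_movie`."""
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        frame_interval=float(meta.get("frame_interval_s", 0.5)),
        pixel_size=float(meta.get("pixel_size_nm", 135.0)),
        recenter_frames=list(meta.get("recenter_frames", [])),
        origins=np.asarray(meta["origins_nm"]) if "origins_nm" in meta else None,
    )
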