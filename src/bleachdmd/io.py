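"""Reading and writing multi-page TIFF stacks, masks and tables."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile

from .stack import BleachStack

__all__ = ["read_stack", "write_stack", "read_mask", "write_mask"]


def _metadata_dt(tif: tifffile.TiffFile) -> float | None:
    # ImageJ-style stacks record the frame interval as 'finterval'.
    meta = tif.imagej_metadata or {}
    dt = meta.get("finterval")
    if dt is not None and dt > 0:
        return float(dt)
    return None


def read_stack(path, dt: float | None = None) -> BleachStack:
    """Load a multi-page grayscale TIFF as a bleach stack.

    Frames are ordered by page index.  The frame interval is taken from
    the ``dt`` argument; if absent, from ImageJ TIFF metadata
    (``finterval``); otherwise it defaults to 1.0 s with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_dt = _metadata_dt(tif)
    if arr.ndim == 2:
        raise ValueError(f"{path} is a single image; a bleach stack needs >= 2 frames")
    if arr.ndim != 3:
        raise ValueError(
            f"{path} has shape {arr.shape}; expected multi-page grayscale "
            "(RGB/multi-channel stacks are not supported)"
        )
    if arr.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
        raise ValueError(f"unsupported pixel dtype {arr.dtype}")
    if dt is None:
        dt = meta_dt
    if dt is None:
        warnings.warn("no frame interval given or found in metadata; assuming dt = 1.0 s", stacklevel=2)
        dt = 1.0
    return BleachStack(frames=arr, dt=dt)


def write_stack(stack: BleachStack, path, dtype=None) -> Path:
    """Write a stack as a multi-page TIFF, one page per frame.

    Float data defaults to 32-bit float (lossless for reconstructions);
    integer targets are clipped to their range with a warning if values
    fall outside it.
    """
    path = Path(path)
    frames = stack.frames
    if frames.size == 0:
        raise ValueError("refusing to write an empty stack")
    if dtype is None:
        dtype = frames.dtype if frames.dtype in (np.uint8, np.uint16) else np.float32
    dtype = np.dtype(dtype)
    if dtype.kind == "u":
        lo, hi = 0, np.iinfo(dtype).max
        if frames.min() < lo or frames.max() > hi:
            warnings.warn(
                f"values outside [{lo}, {hi}] clipped when writing {dtype} TIFF",
                stacklevel=2,
            )
        out = np.clip(np.round(frames), lo, hi).astype(dtype)
    else:
        out = frames.astype(dtype)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        out,
        imagej=True,
        metadata={"axes": "TYX", "finterval": stack.dt},
    )
    return path


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a binary mask as a 1-page 8-bit TIFF (0 / 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask(path) -> np.ndarray:
    """Read a binary mask image (any nonzero pixel is foreground)."""
    return np.asarray(tifffile.imread(Path(path))) > 0
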