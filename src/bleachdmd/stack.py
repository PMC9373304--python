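"""Containers for bleach stacks and their space-time matrix form.

A *bleach stack* is a time-lapse fluorescence image series acquired under
continuous illumination, so that intensity decays frame to frame through
photobleaching.  Dynamic mode decomposition operates not on the stack
itself but on its *space-time matrix*: each frame is flattened row-major
into a column vector and the columns are laid out in acquisition order,
giving an ``n x m`` matrix (``n`` pixels, ``m`` frames).  The flattening
is lossless and is inverted by :func:`unreshape`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BleachStack", "SpaceTimeMatrix", "reshape_stack", "unreshape"]


@dataclass
class BleachStack:
    """A 3D intensity array with a constant frame interval.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; one page per time
        point, in acquisition order.
    dt
        Frame interval in seconds (> 0).
    """

    frames: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"expected a (n_frames, height, width) array, got shape {self.frames.shape}"
            )
        if self.dt <= 0:
            raise ValueError(f"frame interval dt must be positive, got {self.dt}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds, first frame at t = 0."""
        return np.arange(self.n_frames) * self.dt

    def __getitem__(self, k):
        return self.frames[k]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class SpaceTimeMatrix:
    """The ``n x m`` data matrix X whose columns are flattened frames."""

    data: np.ndarray
    frame_shape: tuple[int, int]
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        h, w = self.frame_shape
        if self.data.ndim != 2 or self.data.shape[0] != h * w:
            raise ValueError(
                f"data has shape {self.data.shape}, expected ({h * w}, m) "
                f"for frame shape {self.frame_shape}"
            )

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def reshape_stack(stack: BleachStack) -> SpaceTimeMatrix:
    """Flatten a stack into its space-time matrix.

    Column ``k`` is frame ``k`` flattened row-major: all pixels of image
    row 0 first, then row 1, and so on.  The dtype is promoted to
    floating point so downstream linear algebra does not overflow the
    integer camera dtype.
    """
    if stack.n_frames < 2:
        raise ValueError("a bleach stack needs at least 2 frames to analyse dynamics")
    m = stack.n_frames
    data = stack.frames.reshape(m, -1).T.astype(np.float64)
    return SpaceTimeMatrix(data=data, frame_shape=stack.frame_shape, dt=stack.dt)


def unreshape(matrix, frame_shape: tuple[int, int] | None = None, dt: float | None = None):
    """Invert :func:`reshape_stack`.

    Accepts either a :class:`SpaceTimeMatrix` (returns a
    :class:`BleachStack`), a 2D ``(n, m)`` array with ``frame_shape``
    given (returns a stack), or a single length-``n`` column (returns a
    2D image).  A complex column is returned as a ``(real, imag)`` pair
    of images, since mode-weight columns are complex in general.
    """
    if isinstance(matrix, SpaceTimeMatrix):
        frame_shape = matrix.frame_shape
        dt = matrix.dt if dt is None else dt
        matrix = matrix.data
    if frame_shape is None:
        raise ValueError("frame_shape is required when passing a bare array")
    arr = np.asarray(matrix)
    h, w = frame_shape
    if arr.ndim == 1:
        if arr.size != h * w:
            raise ValueError(f"column length {arr.size} incompatible with frame shape {frame_shape}")
        if np.iscomplexobj(arr):
            return arr.real.reshape(h, w), arr.imag.reshape(h, w)
        return arr.reshape(h, w)
    if arr.ndim != 2 or arr.shape[0] != h * w:
        raise ValueError(f"matrix shape {arr.shape} incompatible with frame shape {frame_shape}")
    frames = arr.T.reshape(arr.shape[1], h, w)
    return BleachStack(frames=frames, dt=1.0 if dt is None else dt)
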