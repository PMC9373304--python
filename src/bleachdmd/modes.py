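"""Turning a fitted DMD back into images, videos and fluorophore groups.

Each DMD mode is a spatial weight map paired with one temporal behaviour
(a decay rate and possibly an oscillation frequency).  Reconstruction is
the finite expansion ``x_k = sum_j phi_j lambda_j^{k-1} b_j``; restricting
the sum to a subset of modes isolates the image content that follows the
corresponding kinetics, which is how spectrally indistinguishable
fluorophores (or a probe versus autofluorescence) are separated purely by
their bleaching behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dmd import DMDModel
from .stack import BleachStack

__all__ = [
    "ModeMap",
    "ModeGroup",
    "reconstruct",
    "mode_weight_maps",
    "classify_modes",
    "group_reconstruct",
    "default_mode_groups",
    "render_overlay",
]

#: Imaginary residue (relative to max intensity) above which a
#: reconstruction warns about broken conjugate pairing.
IMAG_RESIDUE_WARN = 1e-6


@dataclass
class ModeMap:
    """The 2D weight images of one dynamic mode."""

    mode_index: int
    real_image: np.ndarray
    imag_image: np.ndarray
    omega: complex
    amplitude: complex

    @property
    def contribution_image(self) -> np.ndarray:
        """Re(phi_j * b_j) on the pixel grid.

        This is the mode's contribution to the first frame, so it is
        positive wherever the mode describes real signal, regardless of
        the (arbitrary) phase convention of the eigenvector.  It is the
        map used for histogram thresholding.
        """
        return (
            self.real_image * self.amplitude.real
            - self.imag_image * self.amplitude.imag
        )


@dataclass
class ModeGroup:
    """A named subset of mode indices (e.g. "probe", "autofluorescence")."""

    label: str
    mode_indices: list[int]

    def __post_init__(self) -> None:
        if len(set(self.mode_indices)) != len(self.mode_indices):
            raise ValueError("mode indices within a group must be unique")


def _check_subset(model: DMDModel, which) -> np.ndarray:
    if which is None:
        return np.arange(model.rank)
    idx = np.asarray(which, dtype=int)
    if idx.size == 0:
        raise ValueError("mode subset must not be empty")
    if idx.min() < 0 or idx.max() >= model.rank:
        raise ValueError(f"mode indices must lie in [0, {model.rank - 1}]")
    return idx


def reconstruct(
    model: DMDModel,
    n_frames: int | None = None,
    which_modes=None,
) -> BleachStack:
    """Reconstruct a (possibly mode-restricted) bleach stack.

    Frame ``k`` (0-based) is the real part of
    ``sum_j phi_j lambda_j^k b_j`` over the selected modes, reshaped to
    the frame grid.  The default reconstructs all modes over the
    training duration.
    """
    if n_frames is None:
        n_frames = model.n_train_frames
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    idx = _check_subset(model, which_modes)

    lam = model.eigenvalues[idx]
    powers = lam[None, :] ** np.arange(n_frames)[:, None]        # (m, r')
    coeffs = powers * model.amplitudes[idx][None, :]             # (m, r')
    X = model.modes[:, idx] @ coeffs.T                           # (n, m)

    peak = np.abs(X.real).max()
    residue = np.abs(X.imag).max()
    if peak > 0 and residue > IMAG_RESIDUE_WARN * peak:
        warnings.warn(
            f"imaginary residue {residue:.3g} exceeds {IMAG_RESIDUE_WARN:g} of the "
            "peak intensity; conjugate mode pairing may be broken",
            RuntimeWarning,
            stacklevel=2,
        )
    frames = X.real.T.reshape(n_frames, *model.frame_shape)
    return BleachStack(frames=frames, dt=model.dt)


def mode_weight_maps(model: DMDModel) -> list[ModeMap]:
    """One :class:`ModeMap` per mode, real and imaginary parts split."""
    out = []
    for j in range(model.rank):
        img = model.mode_image(j)
        out.append(
            ModeMap(
                mode_index=j,
                real_image=img.real.copy(),
                imag_image=img.imag.copy(),
                omega=complex(model.omegas[j]),
                amplitude=complex(model.amplitudes[j]),
            )
        )
    return out


def classify_modes(model: DMDModel, tol: float = 1e-6) -> list[str]:
    """Label each mode oscillatory / decaying / constant / growing.

    A mode is oscillatory iff ``|Im omega| > tol``; otherwise it is
    decaying, growing or constant by the sign of ``Re omega`` against
    the same tolerance (in 1/s).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    labels = []
    for om in model.omegas:
        if abs(om.imag) > tol:
            labels.append("oscillatory")
        elif om.real < -tol:
            labels.append("decaying")
        elif om.real > tol:
            labels.append("growing")
        else:
            labels.append("constant")
    return labels


def group_reconstruct(
    model: DMDModel,
    groups: list[ModeGroup],
    n_frames: int | None = None,
) -> dict[str, BleachStack]:
    """Reconstruct one stack per mode group (groups need not partition)."""
    return {
        g.label: reconstruct(model, n_frames=n_frames, which_modes=g.mode_indices)
        for g in groups
    }


def default_mode_groups(model: DMDModel, tol: float = 1e-6) -> list[ModeGroup]:
    """Heuristic probe / background split of the decaying modes.

    The slowest-decaying non-oscillatory mode (Re omega closest to 0)
    is labelled background/autofluorescence — in stained specimens the
    endogenous fluorescence bleaches much more slowly than the probe —
    and every other decaying mode is labelled probe.  Constant modes
    join the background group.  Always overridable by passing explicit
    :class:`ModeGroup` lists to :func:`group_reconstruct`.
    """
    labels = classify_modes(model, tol=tol)
    decaying = [j for j, l in enumerate(labels) if l == "decaying"]
    constant = [j for j, l in enumerate(labels) if l == "constant"]
    if not decaying:
        raise ValueError("no decaying modes to group")
    slowest = max(decaying, key=lambda j: model.omegas[j].real)
    background = sorted(constant + [slowest])
    probe = [j for j in decaying if j != slowest]
    groups = [ModeGroup("background", background)]
    if probe:
        groups.append(ModeGroup("probe", probe))
    return groups


def render_overlay(
    group_a: BleachStack,
    group_b: BleachStack,
    frame_index: int,
) -> np.ndarray:
    """Two-channel RGB overlay of one frame from two group stacks.

    Channel 0 (red) is the min-max-scaled frame of ``group_a``, channel
    1 (green) of ``group_b``, channel 2 is zero.  Scaling bounds are
    taken over each *whole stack*, so bleaching stays visible across
    frames instead of being renormalized away.
    """
    if group_a.frames.shape != group_b.frames.shape:
        raise ValueError("overlay stacks must have identical shapes")
    if not 0 <= frame_index < group_a.n_frames:
        raise ValueError(f"frame_index {frame_index} out of range")

    def scaled(stack: BleachStack) -> np.ndarray:
        lo, hi = stack.frames.min(), stack.frames.max()
        span = hi - lo
        if span == 0:
            return np.zeros(stack.frame_shape)
        return (stack.frames[frame_index] - lo) / span

    h, w = group_a.frame_shape
    rgb = np.zeros((h, w, 3))
    rgb[..., 0] = scaled(group_a)
    rgb[..., 1] = scaled(group_b)
    return rgb
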