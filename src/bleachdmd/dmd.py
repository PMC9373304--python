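"""Exact dynamic mode decomposition of bleach stacks.

DMD approximates the linear transfer (Koopman) operator ``A`` that
advances one flattened frame to the next, ``x_{k+1} = A x_k``, directly
from data.  With the snapshot matrix split into time-shifted halves
``X1`` (frames 1..m-1) and ``X2`` (frames 2..m), the best-fit operator
is ``A = X2 pinv(X1)``.  Working in the rank-``r`` left-singular basis
of ``X1`` gives the reduced operator

    A' = U'* X2 V' S'^{-1},

whose eigenvalues equal those of ``A``; the *exact modes* are
``Phi = X2 V' S'^{-1} W`` with ``A' W = W L``.  Each eigenvalue
``lambda_j`` maps to a continuous rate ``omega_j = log(lambda_j)/dt``
whose real part is the decay (bleach) rate and whose imaginary part is
an oscillation frequency.

Rank selection follows the optimal singular-value hard threshold for
unknown noise (median-based): singular values above
``omega(beta) * median(sigma)`` are kept, where ``beta`` is the matrix
aspect ratio and ``omega(beta)`` is calibrated against the median of the
Marchenko-Pastur distribution.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, optimize

from .stack import BleachStack, SpaceTimeMatrix, reshape_stack

__all__ = [
    "ShiftPair",
    "DMDModel",
    "shift_matrices",
    "select_rank",
    "fit_dmd",
    "to_continuous_eigs",
]

#: Relative floor below which singular values are treated as exactly zero.
SINGULAR_VALUE_FLOOR = 1e-12


class ShiftPair(NamedTuple):
    """The discrete time-shifted snapshot matrices X1 and X2."""

    X1: np.ndarray
    X2: np.ndarray


def shift_matrices(matrix: SpaceTimeMatrix) -> ShiftPair:
    """Split X into X1 (drop last column) and X2 (drop first column)."""
    X = matrix.data
    if X.shape[1] < 2:
        raise ValueError("need at least 2 frames to form shifted snapshot matrices")
    return ShiftPair(X1=X[:, :-1], X2=X[:, 1:])


@functools.lru_cache(maxsize=None)
def _mp_median(beta: float) -> float:
    """Median of the Marchenko-Pastur distribution with aspect ratio beta."""
    lo = (1 - np.sqrt(beta)) ** 2
    hi = (1 + np.sqrt(beta)) ** 2

    def dens(x):
        return np.sqrt((hi - x) * (x - lo)) / (2 * np.pi * beta * x)

    def cdf(x):
        return integrate.quad(dens, lo, x)[0]

    return optimize.brentq(lambda x: cdf(x) - 0.5, lo + 1e-12, hi - 1e-12)


def select_rank(singular_values, shape, rank: int | None = None) -> int:
    """Truncation rank by the optimal hard threshold for unknown noise.

    Parameters
    ----------
    singular_values
        Descending singular values of X1.
    shape
        ``(n, m)`` shape of the matrix the spectrum came from.
    rank
        A user-supplied fixed rank; when given it overrides the
        automatic threshold entirely.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular value spectrum")
    if rank is not None:
        if rank < 1:
            raise ValueError("rank must be >= 1")
        return int(min(rank, s.size))
    if not np.any(s > 0):
        raise ValueError("all singular values are zero; nothing to decompose")
    n, m = shape
    beta = min(n, m) / max(n, m)
    lam = np.sqrt(2 * (beta + 1) + 8 * beta / (beta + 1 + np.sqrt(beta**2 + 14 * beta + 1)))
    tau = lam / np.sqrt(_mp_median(beta)) * np.median(s)
    # numerically-zero singular values never count, even if the median
    # (and hence the threshold) collapses to zero on noiseless data
    r = int(np.sum(s > max(tau, SINGULAR_VALUE_FLOOR * s[0])))
    return max(1, min(r, s.size))


def to_continuous_eigs(lambdas, dt: float) -> np.ndarray:
    """Map discrete eigenvalues to continuous rates: omega = log(lambda)/dt.

    Uses the principal branch of the complex logarithm, so oscillations
    faster than pi/dt alias.  Real lambda in (0, 1) gives a real,
    negative omega (a pure decay).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam = np.asarray(lambdas, dtype=complex)
    if np.any(lam == 0):
        raise ValueError("zero eigenvalue has no finite continuous counterpart")
    return np.log(lam) / dt


@dataclass
class DMDModel:
    """A fitted exact-DMD decomposition.

    ``modes`` has unit-norm columns; the overall scale of each mode is
    carried by its amplitude, so the reconstruction
    ``x_k = sum_j phi_j lambda_j^{k-1} b_j`` is invariant to the
    normalization.  Modes are ordered deterministically: oscillatory
    modes first (descending \\|Im omega\\|, the +Im member of each
    conjugate pair first), then the remaining modes by descending
    Re omega (slowest decay first).
    """

    rank: int
    eigenvalues: np.ndarray
    omegas: np.ndarray
    modes: np.ndarray
    amplitudes: np.ndarray
    eigvecs: np.ndarray
    singular_values: np.ndarray
    dt: float
    frame_shape: tuple[int, int]
    n_train_frames: int

    @property
    def decay_rates(self) -> np.ndarray:
        """Re(omega): bleach (decay) rate of each mode, in 1/s."""
        return self.omegas.real

    def mode_image(self, j: int) -> np.ndarray:
        """Mode j reshaped to the frame grid (complex 2D image)."""
        return self.modes[:, j].reshape(self.frame_shape)


_OSC_TOL_SCALE = 1e-9  # |Im omega| above 1e-9/dt counts as oscillatory for ordering


def _mode_order(omegas: np.ndarray, dt: float) -> np.ndarray:
    tol = _OSC_TOL_SCALE / dt
    osc = np.abs(omegas.imag) > tol

    def key(j):
        if osc[j]:
            return (0, -abs(omegas[j].imag), -np.sign(omegas[j].imag), -omegas[j].real)
        return (1, -omegas[j].real, 0.0, 0.0)

    return np.array(sorted(range(len(omegas)), key=key), dtype=int)


def fit_dmd(stack, rank: int | None = None) -> DMDModel:
    """Fit an exact DMD to a bleach stack (or space-time matrix).

    Parameters
    ----------
    stack
        A :class:`BleachStack` or :class:`SpaceTimeMatrix` with at
        least 3 frames of finite values.
    rank
        Fixed truncation rank; ``None`` selects it automatically by the
        median-based optimal hard threshold.
    """
    matrix = reshape_stack(stack) if isinstance(stack, BleachStack) else stack
    X = matrix.data
    n, m = X.shape
    if m < 3:
        raise ValueError("need at least 3 frames to fit dynamics")
    if not np.all(np.isfinite(X)):
        raise ValueError("stack contains non-finite values")
    if rank is not None and rank > m - 1:
        raise ValueError(f"rank {rank} exceeds the maximum m-1 = {m - 1}")

    X1, X2 = shift_matrices(matrix)
    U, s, Vh = np.linalg.svd(X1, full_matrices=False)
    r = select_rank(s, X1.shape, rank=rank)
    if s[r - 1] <= SINGULAR_VALUE_FLOOR * s[0]:
        raise ValueError(
            f"singular value {r} is numerically zero relative to the largest; "
            "lower the rank"
        )
    Ur, sr, Vr = U[:, :r], s[:r], Vh[:r].conj().T

    # Reduced operator and its spectral decomposition.
    Atilde = Ur.conj().T @ X2 @ Vr / sr
    eigvals, W = np.linalg.eig(Atilde)

    # Exact modes, normalized to unit column norm (scale moves into b).
    Phi = X2 @ Vr @ np.diag(1.0 / sr) @ W
    norms = np.linalg.norm(Phi, axis=0)
    norms[norms == 0] = 1.0
    Phi = Phi / norms

    # Amplitudes anchor the expansion at the first snapshot.
    b, *_ = np.linalg.lstsq(Phi, X[:, 0].astype(complex), rcond=None)

    omegas = to_continuous_eigs(eigvals, matrix.dt)
    order = _mode_order(omegas, matrix.dt)
    eigvals, omegas, b, W = eigvals[order], omegas[order], b[order], W[:, order]
    Phi = Phi[:, order]

    # Phase convention: flip mode/amplitude pairs so Re(b) >= 0 — the
    # product phi_j * b_j (and hence any reconstruction) is unchanged.
    flip = b.real < 0
    Phi[:, flip] *= -1
    b[flip] *= -1

    return DMDModel(
        rank=r,
        eigenvalues=eigvals,
        omegas=omegas,
        modes=Phi,
        amplitudes=b,
        eigvecs=W,
        singular_values=s,
        dt=matrix.dt,
        frame_shape=matrix.frame_shape,
        n_train_frames=m,
    )
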