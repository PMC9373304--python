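"""Synthetic bleach-stack generator with known kinetics and ground truth.

The generator emulates a validation stack widely used for bleaching-based
segmentation: an 8-bit movie with a dim noisy background (mean 10) in
which a bright rectangle (initial mean 190) encloses a circle and an
ellipse, every region decaying mono-exponentially at its own rate
(defaults 0.01, 0.05 and 0.15 s^-1).  All three regions start at the
same intensity, so no single frame can be segmented by intensity alone —
only the kinetics distinguish them.

Noise model.  By default detection is *shot-noise limited*: each pixel
value is a Poisson draw with mean equal to the local expected
fluorescence ``F(p) * exp(-k(p) t)``.  The background is modelled as dim
fluorescence from the same bleachable pool as the main region and
therefore fades at the base (slowest) rate; this gives the stack exactly
one kinetic component per decay rate, which is what makes automated rank
selection and mode-map thresholding behave the way they should on clean
data.  A static background (``background_rate=0``), the additive
constant-floor Poisson model, uniform noise, and a noiseless mode are
all available through :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .stack import BleachStack

__all__ = [
    "RegionSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_stack",
    "decay_profile",
]

_SHAPES = ("rectangle", "circle", "ellipse")


@dataclass
class RegionSpec:
    """One geometric region with its own bleaching kinetics.

    ``geometry`` uses 0-based (row, column) pixel coordinates:

    - rectangle: ``(row0, col0, height, width)``
    - circle: ``(row_center, col_center, radius)``
    - ellipse: ``(row_center, col_center, semi_row, semi_col)``
    """

    shape: str
    geometry: tuple
    initial_mean: float
    rate_constant: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {_SHAPES}")
        self.geometry = tuple(float(g) for g in self.geometry)
        n_expected = {"rectangle": 4, "circle": 3, "ellipse": 4}[self.shape]
        if len(self.geometry) != n_expected:
            raise ValueError(f"{self.shape} geometry needs {n_expected} numbers, got {len(self.geometry)}")
        if self.initial_mean < 0:
            raise ValueError("initial_mean must be >= 0")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        if not self.label:
            self.label = self.shape

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Binary membership mask of this region on the pixel grid."""
        h, w = frame_shape
        rr, cc = np.mgrid[0:h, 0:w]
        if self.shape == "rectangle":
            r0, c0, rh, rw = self.geometry
            return (rr >= r0) & (rr < r0 + rh) & (cc >= c0) & (cc < c0 + rw)
        if self.shape == "circle":
            rc, cf, rad = self.geometry
            return (rr - rc) ** 2 + (cc - cf) ** 2 <= rad**2
        rc, cf, sr, sc = self.geometry
        return ((rr - rc) / sr) ** 2 + ((cc - cf) / sc) ** 2 <= 1.0

    def bounds(self) -> tuple[float, float, float, float]:
        """(row_min, row_max, col_min, col_max) of the bounding box."""
        if self.shape == "rectangle":
            r0, c0, rh, rw = self.geometry
            return r0, r0 + rh - 1, c0, c0 + rw - 1
        if self.shape == "circle":
            rc, cf, rad = self.geometry
            return rc - rad, rc + rad, cf - rad, cf + rad
        rc, cf, sr, sc = self.geometry
        return rc - sr, rc + sr, cf - sc, cf + sc


def _default_regions() -> list[RegionSpec]:
    # 160x120 frame, rectangle with a 10 px margin, circle and ellipse
    # placed non-overlapping inside it; all regions start at mean 190.
    return [
        RegionSpec("rectangle", (10, 10, 100, 140), 190.0, 0.01),
        RegionSpec("circle", (60, 50, 18), 190.0, 0.05),
        RegionSpec("ellipse", (60, 110, 13, 26), 190.0, 0.15),
    ]


@dataclass
class SimConfig:
    """Full description of a synthetic bleach stack.

    The defaults are the canonical validation stack: 160x120 pixels,
    100 frames at dt = 1 s, 8-bit, background mean 10, three regions of
    initial mean 190 decaying at 0.01 / 0.05 / 0.15 s^-1.

    ``background_rate=None`` means the background bleaches at the
    slowest region rate (dim fluorescence from the same pool); pass 0
    for a static noise floor.  ``noise`` is one of ``"shot"`` (Poisson
    counts with mean = expected fluorescence), ``"additive-poisson"``
    (signal plus a constant Poisson floor of mean ``background_mean``),
    ``"uniform"`` (signal plus uniform integers on [0, 2*background_mean])
    or ``"none"``.
    """

    width: int = 160
    height: int = 120
    n_frames: int = 100
    dt: float = 1.0
    bit_depth: int = 8
    background_mean: float = 10.0
    background_rate: float | None = None
    regions: list[RegionSpec] = field(default_factory=_default_regions)
    noise: str = "shot"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.n_frames) < 1:
            raise ValueError("width, height and n_frames must all be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not 0 <= self.background_mean <= 2**self.bit_depth - 1:
            raise ValueError("background_mean must be representable at the given bit depth")
        if self.noise not in ("shot", "additive-poisson", "uniform", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        self.regions = [
            r if isinstance(r, RegionSpec) else RegionSpec(**r) for r in self.regions
        ]
        self._validate_geometry()

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def _validate_geometry(self) -> None:
        masks = []
        for reg in self.regions:
            rmin, rmax, cmin, cmax = reg.bounds()
            if rmin < 0 or cmin < 0 or rmax > self.height - 1 or cmax > self.width - 1:
                raise ValueError(f"region {reg.label!r} extends outside the {self.height}x{self.width} frame")
            masks.append(reg.mask(self.frame_shape))
        # Regions are listed outer-to-inner: a later region may be fully
        # contained in an earlier one (and overrides it), but partial
        # overlap is ambiguous and rejected.
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                inter = masks[i] & masks[j]
                if inter.any() and not (inter == masks[j]).all():
                    raise ValueError(
                        f"regions {self.regions[i].label!r} and {self.regions[j].label!r} "
                        "partially overlap; list regions outer-to-inner"
                    )

    def resolved_background_rate(self) -> float:
        if self.background_rate is not None:
            return float(self.background_rate)
        if not self.regions:
            return 0.0
        return min(r.rate_constant for r in self.regions)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        for r in d["regions"]:
            r["geometry"] = list(r["geometry"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-region binary masks (pairwise disjoint) and the true rate map.

    ``masks`` maps each region label to the pixels that follow *that
    region's* kinetics: an outer region's mask excludes any inner region
    carved into it (e.g. rectangle-minus-circle-minus-ellipse).
    """

    masks: dict[str, np.ndarray]
    rate_map: np.ndarray
    background_mask: np.ndarray

    def region_labels(self) -> list[str]:
        return list(self.masks)


def _ground_truth(config: SimConfig) -> GroundTruth:
    shape = config.frame_shape
    raw = [r.mask(shape) for r in config.regions]
    masks: dict[str, np.ndarray] = {}
    for i, reg in enumerate(config.regions):
        m = raw[i].copy()
        for j in range(i + 1, len(raw)):
            m &= ~raw[j]
        masks[reg.label] = m
    bg = np.ones(shape, dtype=bool)
    for m in masks.values():
        bg &= ~m
    rate_map = np.full(shape, config.resolved_background_rate(), dtype=float)
    for reg, m in zip(config.regions, masks.values()):
        rate_map[m] = reg.rate_constant
    return GroundTruth(masks=masks, rate_map=rate_map, background_mask=bg)


def _expected_intensity(config: SimConfig, truth: GroundTruth) -> np.ndarray:
    """(n_frames, h, w) array of expected fluorescence F(p)·exp(-k(p) t)."""
    F = np.full(config.frame_shape, config.background_mean, dtype=float)
    for reg, m in zip(config.regions, truth.masks.values()):
        F[m] = reg.initial_mean
    t = np.arange(config.n_frames) * config.dt
    return F[None] * np.exp(-truth.rate_map[None] * t[:, None, None])


def simulate_stack(config: SimConfig) -> tuple[BleachStack, GroundTruth]:
    """Generate a synthetic bleach stack and its ground truth.

    The result is deterministic for a given ``config`` (including its
    ``seed``).  Every frame is quantized to ``bit_depth`` integers with
    clipping; with ``noise="none"`` masked region means equal the
    closed-form :func:`decay_profile` to within quantization (0.5).
    """
    truth = _ground_truth(config)
    mu = _expected_intensity(config, truth)
    rng = np.random.default_rng(config.seed)
    maxv = 2**config.bit_depth - 1

    if config.noise == "shot":
        raw = rng.poisson(mu).astype(float)
    elif config.noise == "none":
        raw = np.round(mu)
    else:
        # Additive models: decaying signal in the regions only, plus a
        # constant random floor of mean background_mean everywhere.
        signal = mu.copy()
        signal[:, truth.background_mask] = 0.0
        if config.noise == "additive-poisson":
            floor = rng.poisson(config.background_mean, size=mu.shape)
        else:  # uniform
            floor = rng.integers(0, int(round(2 * config.background_mean)) + 1, size=mu.shape)
        raw = np.round(signal + floor)

    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    frames = np.clip(raw, 0, maxv).astype(dtype)
    return BleachStack(frames=frames, dt=config.dt), truth


def decay_profile(region: RegionSpec, times) -> np.ndarray:
    """Closed-form expected intensity ``initial_mean * exp(-rate * t)``.

    ``times`` must be sorted and non-negative.  The profile is strictly
    non-increasing whenever the rate is positive; it is the noiseless
    oracle against which simulated region means are checked.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be a 1D vector")
    if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
        raise ValueError("times must be sorted and non-negative")
    return region.initial_mean * np.exp(-region.rate_constant * t)
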