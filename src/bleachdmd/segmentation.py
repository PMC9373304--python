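"""Histogram thresholding of mode-weight and rate maps, with overlap scores.

A decaying DMD mode contributes only where its kinetics are present, so
thresholding the mode's contribution map segments the image into regions
of distinct bleaching behaviour even when every region starts at the
same intensity.  The classical histogram methods (Otsu, Isodata, Li,
Yen, Mean, Minimum, Triangle, multi-Otsu) are delegated to
``skimage.filters``; all histogram-based methods use 256 bins over the
map's min-max range.  Segmentation quality against ground truth is
scored with the Jaccard index J = |A∩B|/|A∪B| and the Dice score
D = 2|A∩B|/(|A|+|B|) = 2J/(1+J).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters

from .dmd import DMDModel
from .modes import classify_modes, mode_weight_maps

__all__ = [
    "SegMask",
    "THRESHOLD_METHODS",
    "threshold_map",
    "multi_otsu_map",
    "jaccard",
    "dice",
    "evaluate_modes",
]

NBINS = 256

# method name -> (skimage callable, accepts nbins)
THRESHOLD_METHODS = {
    "otsu": (filters.threshold_otsu, True),
    "isodata": (filters.threshold_isodata, True),
    "li": (filters.threshold_li, False),
    "yen": (filters.threshold_yen, True),
    "mean": (filters.threshold_mean, False),
    "minimum": (filters.threshold_minimum, True),
    "triangle": (filters.threshold_triangle, True),
}


@dataclass
class SegMask:
    """A binary segmentation and the threshold that produced it."""

    mask: np.ndarray
    method: str
    threshold: float
    source: str = ""


def threshold_map(map2d: np.ndarray, method: str = "otsu", source: str = "") -> SegMask:
    """Threshold a 2D map; foreground = pixels strictly above threshold.

    For mode maps pass the orientation-invariant contribution image
    (``ModeMap.contribution_image``), in which contributing regions are
    high-valued; rate and time-constant maps are used as-is.  The
    Minimum method smooths the 256-bin histogram with a 3-tap mean
    until exactly two maxima remain and takes the valley between them;
    if bimodality is never reached it raises.
    """
    arr = np.asarray(map2d, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D map")
    if not np.all(np.isfinite(arr)):
        raise ValueError("map contains non-finite values")
    if arr.max() == arr.min():
        raise ValueError("constant map cannot be thresholded")
    try:
        fn, has_nbins = THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(THRESHOLD_METHODS)}"
        ) from None
    thr = fn(arr, nbins=NBINS) if has_nbins else fn(arr)
    return SegMask(mask=arr > thr, method=method, threshold=float(thr), source=source)


def multi_otsu_map(map2d: np.ndarray, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Multi-class Otsu: maximize between-class variance over n_classes.

    Returns ``(label_image, thresholds)`` with ``n_classes - 1``
    ascending thresholds.
    """
    arr = np.asarray(map2d, dtype=float)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    thresholds = filters.threshold_multiotsu(arr, classes=n_classes, nbins=NBINS)
    labels = np.digitize(arr, bins=thresholds)
    return labels, thresholds


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def jaccard(pred, truth) -> float:
    """|A∩B| / |A∪B|; defined as 1.0 when both masks are empty."""
    a, b = _as_bool(pred), _as_bool(truth)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(pred, truth) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    a, b = _as_bool(pred), _as_bool(truth)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2 * np.logical_and(a, b).sum() / total)


def evaluate_modes(
    model: DMDModel,
    ground_truth_masks: dict[str, np.ndarray],
    methods=("otsu", "isodata", "li", "yen", "mean", "minimum", "triangle"),
) -> pd.DataFrame:
    """Score thresholded decaying-mode maps against ground-truth regions.

    For every (decaying mode, method) pair the mode's contribution map
    is thresholded and scored against the *best-matching* ground-truth
    region (maximal Jaccard) — mode numbering is eigensolver-dependent,
    so regions are matched by overlap, not by index.  Returns a tidy
    table with one row per pair.
    """
    labels = classify_modes(model)
    decaying = [j for j, l in enumerate(labels) if l == "decaying"]
    if not decaying:
        raise ValueError("model has no decaying modes to evaluate")
    maps = mode_weight_maps(model)
    rows = []
    for j in decaying:
        cmap = maps[j].contribution_image
        for method in methods:
            seg = threshold_map(cmap, method=method, source=f"mode {j}")
            scores = {name: jaccard(seg.mask, m) for name, m in ground_truth_masks.items()}
            region = max(scores, key=scores.get)
            rows.append(
                {
                    "mode_index": j,
                    "omega": model.omegas[j].real,
                    "method": method,
                    "region": region,
                    "threshold": seg.threshold,
                    "jaccard": scores[region],
                    "dice": dice(seg.mask, ground_truth_masks[region]),
                }
            )
    return pd.DataFrame(rows)
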