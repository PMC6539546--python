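"""Coarse detection stage: per-pixel color Naive Bayes and ROI extraction.

Mature tomatoes are red on green foliage, so three color transforms separate
them well: R-G, R-B, and the red chromaticity R/(R+G+B). A Gaussian Naive
Bayes classifier over these features labels every pixel tomato/background;
the binary mask is cleaned by morphological opening and closing, and the
bounding boxes of the surviving connected components — padded and expanded to
at least one scan window — become the regions of interest handed to the fine
sliding-window stage. On typical scenes this prunes more than half the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from skimage import measure, morphology

from .nms import BoundingBox

__all__ = [
    "NBModel",
    "pixel_color_features",
    "train_nb",
    "nb_log_posterior",
    "classify_pixels",
    "extract_roi",
]

MIN_VARIANCE = 1e-6


def pixel_color_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel (R-G, R-B, R/(R+G+B)); the chromaticity is 0 at black pixels.

    Works on an (H, W, 3) image or an (N, 3) pixel list; the feature axis is
    appended in place of the channel axis.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold RGB channels")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    f3 = np.divide(r, total, out=np.zeros_like(r), where=total > 0)
    return np.stack([r - g, r - b, f3], axis=-1)


@dataclass(frozen=True)
class NBModel:
    """Gaussian class-conditionals per color feature, classes (-1, +1)."""

    means: np.ndarray  # (2, 3), rows ordered (background, tomato)
    variances: np.ndarray  # (2, 3)
    priors: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        if self.means.shape != (2, 3) or self.variances.shape != (2, 3):
            raise ValueError("NBModel expects (2, 3) means and variances")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not math.isclose(float(self.priors.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("priors must sum to 1")


def train_nb(features: np.ndarray, labels: np.ndarray) -> NBModel:
    """Maximum-likelihood Gaussian NB from (N, 3) features and +/-1 labels.

    Variances are floored at 1e-6 so degenerate (constant) features never
    produce a singular likelihood. Per-class samples are put in a canonical
    (sorted) order before accumulating the sufficient statistics, so the
    model is bit-identical under any permutation of the training data.
    """
    X = np.asarray(features, dtype=np.float64).reshape(-1, 3)
    y = np.asarray(labels).astype(np.int64).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    means = np.empty((2, 3))
    variances = np.empty((2, 3))
    priors = np.empty(2)
    for row, cls in enumerate((-1, 1)):
        sel = X[y == cls]
        sel = sel[np.lexsort(sel.T)]
        means[row] = sel.mean(axis=0)
        variances[row] = np.maximum(sel.var(axis=0), MIN_VARIANCE)
        priors[row] = sel.shape[0] / X.shape[0]
    return NBModel(means=means, variances=variances, priors=priors)


def nb_log_posterior(model: NBModel, features: np.ndarray) -> np.ndarray:
    """Unnormalized log-posterior per class; shape (..., 2), (bg, tomato)."""
    X = np.asarray(features, dtype=np.float64)
    diff = X[..., None, :] - model.means  # (..., 2, 3)
    log_lik = -0.5 * np.sum(
        diff**2 / model.variances + np.log(2.0 * np.pi * model.variances), axis=-1
    )
    return log_lik + np.log(model.priors)


def classify_pixels(model: NBModel, image: np.ndarray) -> np.ndarray:
    """Binary mask, white (True) where the tomato posterior wins (ties white)."""
    scores = nb_log_posterior(model, pixel_color_features(image))
    return scores[..., 1] >= scores[..., 0]


def extract_roi(
    mask: np.ndarray,
    window: int = 64,
    pad: int = 16,
    min_area: int = 25,
    footprint_size: int = 3,
) -> List[BoundingBox]:
    """Morphological cleaning + connected components -> scannable regions.

    Opening then closing with a square footprint removes speckle, components
    below ``min_area`` pixels are dropped as noise, and each remaining
    component's bounding box is padded by ``pad`` and grown (shifted if
    necessary) to at least ``window`` on each side within the image.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    footprint = np.ones((footprint_size, footprint_size), dtype=bool)
    cleaned = morphology.closing(morphology.opening(mask, footprint), footprint)

    rois: List[BoundingBox] = []
    for region in measure.regionprops(measure.label(cleaned, connectivity=2)):
        if region.area < min_area:
            continue
        y0, x0, y1, x1 = region.bbox
        x0, y0 = x0 - pad, y0 - pad
        x1, y1 = x1 + pad, y1 + pad
        bw, bh = x1 - x0, y1 - y0
        if bw < window:
            x0 -= (window - bw) // 2
            bw = window
        if bh < window:
            y0 -= (window - bh) // 2
            bh = window
        # shift inside the image, then clip if the image itself is smaller
        x0 = max(0, min(x0, w - bw))
        y0 = max(0, min(y0, h - bh))
        x1 = min(w, x0 + bw)
        y1 = min(h, y0 + bh)
        x0, y0 = max(0, x0), max(0, y0)
        rois.append(BoundingBox(x0, y0, x1 - x0, y1 - y0))
    return rois
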