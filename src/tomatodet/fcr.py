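"""False Color Removal: color-plane filtering of candidate windows.

A window accepted by the shape classifier is binarized with a fixed plane in
RGB space — a pixel is "tomato-colored" when wR*R + wG*G + wB*B + b > 0 — and
kept only if the white-pixel fraction strictly exceeds 0.3. The shipped
default plane, 0.16*R - 0.093*G - 0.037*B - 11.032, was derived from mean
patch colors with a soft-margin separator; ``fit_color_plane`` re-derives
such a plane for other imagery the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "ColorPlane",
    "FcrConfig",
    "DEFAULT_PLANE",
    "binarize_window",
    "white_ratio",
    "fcr_accept",
    "fit_color_plane",
]


@dataclass(frozen=True)
class ColorPlane:
    """Separating plane in RGB space: weights (wR, wG, wB) and bias."""

    weights: Tuple[float, float, float]
    bias: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (3,) or not np.all(np.isfinite(w)) or not np.isfinite(self.bias):
            raise ValueError("plane needs 3 finite weights and a finite bias")
        if np.all(w == 0):
            raise ValueError("plane weights must not all be zero")

    def evaluate(self, rgb: np.ndarray) -> np.ndarray:
        """Signed distance term w.(R,G,B) + b, vectorized over pixels."""
        arr = np.asarray(rgb, dtype=np.float64)
        return arr @ np.asarray(self.weights) + self.bias

    def to_dict(self) -> dict:
        return {"w": [float(v) for v in self.weights], "b": float(self.bias)}

    @classmethod
    def from_dict(cls, d: dict) -> "ColorPlane":
        return cls(tuple(float(v) for v in d["w"]), float(d["b"]))


DEFAULT_PLANE = ColorPlane((0.16, -0.093, -0.037), -11.032)


@dataclass(frozen=True)
class FcrConfig:
    plane: ColorPlane = DEFAULT_PLANE
    binarize_threshold: float = 0.0
    ratio_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio_threshold < 1.0:
            raise ValueError("ratio_threshold must be in (0,1)")


def binarize_window(patch: np.ndarray, plane: ColorPlane = DEFAULT_PLANE,
                    threshold: float = 0.0) -> np.ndarray:
    """Boolean mask: white where the plane responds above the threshold."""
    arr = np.asarray(patch, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) patch, got shape {arr.shape}")
    return plane.evaluate(arr) > threshold


def white_ratio(mask: np.ndarray) -> float:
    """Fraction of white pixels in a non-empty binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("white_ratio of an empty mask is undefined")
    return float(np.count_nonzero(mask)) / mask.size


def fcr_accept(patch: np.ndarray, config: FcrConfig = FcrConfig()) -> bool:
    """Keep the window iff its white-pixel ratio strictly exceeds the threshold."""
    mask = binarize_window(patch, config.plane, config.binarize_threshold)
    return white_ratio(mask) > config.ratio_threshold


def fit_color_plane(means: np.ndarray, labels: np.ndarray, C: float = 1.0) -> ColorPlane:
    """Fit a separating plane from per-sample mean (R, G, B) triplets.

    Solves the soft-margin problem (unweighted slack sum, i.e. C = 1 unless
    overridden) in 3-D RGB space; labels are +1 (tomato) / -1 (background).
    """
    X = np.asarray(means, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64).ravel()
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("means must be (M, 3)")
    if np.unique(y).size < 2:
        raise ValueError("both classes required to fit a plane")
    svc = SVC(kernel="linear", C=C, tol=1e-8)
    svc.fit(X, y)
    w = np.asarray(svc.coef_, dtype=np.float64).ravel()
    b = float(svc.intercept_[0])
    if svc.classes_[1] != 1:
        w, b = -w, -b
    return ColorPlane((float(w[0]), float(w[1]), float(w[2])), b)
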