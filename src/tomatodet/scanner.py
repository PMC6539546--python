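"""Fine detection stage: image pyramid plus ROI-restricted sliding window.

The image is repeatedly downscaled by a factor of 1.1 while it stays at least
113x64 pixels; at every level a 64x64 window slides on a 16-pixel grid over
the regions of interest, each window is classified by HOG + linear SVM, and
accepted windows are optionally filtered by False Color Removal before being
mapped back to original-image coordinates (multiply by 1.1^k, round half-up,
clip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fcr import FcrConfig, binarize_window, white_ratio
from .hog_features import HogConfig, hog_descriptor_batch, to_grayscale
from .linear_svm import LinearModel, decision_function
from .nms import BoundingBox
from .preprocess import resize_bicubic

__all__ = [
    "PyramidSpec",
    "WindowSpec",
    "RawDetection",
    "build_pyramid",
    "slide_windows",
    "scale_roi_to_level",
    "scan",
]


@dataclass(frozen=True)
class PyramidSpec:
    scale_factor: float = 1.1
    min_width: int = 113
    min_height: int = 64

    def __post_init__(self) -> None:
        if self.scale_factor <= 1.0:
            raise ValueError("scale_factor must exceed 1")


@dataclass(frozen=True)
class WindowSpec:
    window: int = 64
    step: int = 16

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class RawDetection:
    """An accepted window mapped back to original-image coordinates."""

    box: BoundingBox
    confidence: float
    pyramid_level: int


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def build_pyramid(
    image: np.ndarray, spec: PyramidSpec = PyramidSpec(), window: int = 64
) -> List[Tuple[np.ndarray, float]]:
    """Levels (scaled image, scale); level k is floor(W/f^k) x floor(H/f^k).

    Levels are included while they stay at least ``min_width x min_height``.
    An image already below the minimum yields a single-level pyramid if it
    still fits the scan window, and fails otherwise.
    """
    h, w = image.shape[:2]
    if w < spec.min_width or h < spec.min_height:
        if w >= window and h >= window:
            return [(image, 1.0)]
        raise ValueError(f"image {w}x{h} smaller than the scan window {window}")
    levels: List[Tuple[np.ndarray, float]] = [(image, 1.0)]
    k = 1
    while True:
        scale = spec.scale_factor**k
        lw, lh = int(w / scale), int(h / scale)
        if lw < spec.min_width or lh < spec.min_height:
            break
        levels.append((resize_bicubic(image, lw, lh), scale))
        k += 1
    return levels


def scale_roi_to_level(roi: BoundingBox, scale: float, level_w: int, level_h: int) -> Optional[BoundingBox]:
    """Map an original-coordinates ROI onto a pyramid level (floor/ceil bounds)."""
    x0 = int(np.floor(roi.x / scale))
    y0 = int(np.floor(roi.y / scale))
    x1 = min(level_w, int(np.ceil(roi.x2 / scale)))
    y1 = min(level_h, int(np.ceil(roi.y2 / scale)))
    if x1 <= x0 or y1 <= y0:
        return None
    return BoundingBox(x0, y0, x1 - x0, y1 - y0)


def slide_windows(
    level_w: int,
    level_h: int,
    winspec: WindowSpec = WindowSpec(),
    rois: Optional[Sequence[BoundingBox]] = None,
) -> List[Tuple[int, int]]:
    """Window origins on the step grid; restricted to ROI overlap if given.

    With ``rois=None`` the whole level is scanned; with an ROI list only
    windows overlapping some ROI by at least one pixel are kept. An empty
    ROI list yields no windows.
    """
    win, step = winspec.window, winspec.step
    if level_w < win or level_h < win:
        return []
    xs = np.arange(0, level_w - win + 1, step)
    ys = np.arange(0, level_h - win + 1, step)
    origins = [(int(x), int(y)) for y in ys for x in xs]
    if rois is None:
        return origins
    kept = []
    for x, y in origins:
        wbox = BoundingBox(x, y, win, win)
        if any(wbox.intersects(r) for r in rois):
            kept.append((x, y))
    return kept


def scan(
    image: np.ndarray,
    model: LinearModel,
    hog_config: HogConfig = HogConfig(),
    fcr_config: Optional[FcrConfig] = None,
    pyramid: PyramidSpec = PyramidSpec(),
    winspec: WindowSpec = WindowSpec(),
    rois: Optional[Sequence[BoundingBox]] = None,
    return_debug: bool = False,
):
    """Run the multi-scale sliding-window detector over an image.

    ``rois=None`` scans exhaustively; otherwise only windows intersecting the
    (per-level rescaled) regions of interest are evaluated. ``fcr_config=None``
    disables False Color Removal — the ablation path. Returns the list of
    :class:`RawDetection`; with ``return_debug=True`` also a per-stage tally.

    Raises if the model was trained under a different HOG configuration
    (detected via the stored config hash).
    """
    if model.hog_config_hash is not None and model.hog_config_hash != hog_config.config_hash():
        raise ValueError("model/HOG configuration mismatch (config hash differs)")
    if not model.is_calibrated:
        raise ValueError("scanning needs a calibrated model for confidences")

    h, w = image.shape[:2]
    win = winspec.window
    detections: List[RawDetection] = []
    debug: Dict[str, object] = {"levels": [], "windows": 0, "svm_rejected": 0,
                                "fcr_rejected": 0, "accepted": 0}

    for level_idx, (level_img, scale) in enumerate(build_pyramid(image, pyramid, win)):
        lh, lw = level_img.shape[:2]
        level_rois = None
        if rois is not None:
            level_rois = [
                r for roi in rois
                if (r := scale_roi_to_level(roi, scale, lw, lh)) is not None
            ]
        origins = slide_windows(lw, lh, winspec, level_rois)
        debug["levels"].append({"level": level_idx, "width": lw, "height": lh,
                                "scale": scale, "windows": len(origins)})
        if not origins:
            continue
        debug["windows"] += len(origins)

        gray = to_grayscale(level_img, hog_config.grayscale_mode)
        patches = np.stack([gray[y:y + win, x:x + win] for x, y in origins])
        descriptors = hog_descriptor_batch(patches, hog_config)
        margins = decision_function(model, descriptors)
        positive = margins >= 0  # margin 0 resolves to the tomato class
        debug["svm_rejected"] += int(np.count_nonzero(~positive))

        conf_scale = model.calibration_scale
        for idx in np.flatnonzero(positive):
            x, y = origins[idx]
            if fcr_config is not None:
                patch = level_img[y:y + win, x:x + win]
                mask = binarize_window(patch, fcr_config.plane, fcr_config.binarize_threshold)
                if white_ratio(mask) <= fcr_config.ratio_threshold:
                    debug["fcr_rejected"] += 1
                    continue
            ox = _round_half_up(x * scale)
            oy = _round_half_up(y * scale)
            side = _round_half_up(win * scale)
            ox, oy = min(ox, w - 1), min(oy, h - 1)
            box = BoundingBox(ox, oy, min(side, w - ox), min(side, h - oy))
            z = np.clip(conf_scale * margins[idx], -500, 500)
            conf = float(1.0 / (1.0 + np.exp(-z)))
            detections.append(RawDetection(box=box, confidence=conf, pyramid_level=level_idx))
            debug["accepted"] += 1

    if return_debug:
        return detections, debug
    return detections
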