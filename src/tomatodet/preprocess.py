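"""Illumination enhancement and resizing.

Every image entering the detector is first normalized against uneven
greenhouse lighting: convert RGB to HSI, compress the intensity channel with
a natural logarithm, apply CLAHE to the compressed intensity, and recombine
with the untouched hue and saturation channels. Images are brought to the
working resolution (360x202 by default) with bicubic interpolation.

Images are plain ``(H, W, 3)`` numpy arrays with values in [0, 255]
(uint8 or float); enhancement returns float64.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage import exposure, transform

__all__ = [
    "HsiImage",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "enhance_illumination",
    "resize_bicubic",
    "DEFAULT_CLIP_LIMIT",
    "DEFAULT_TILE_GRID",
]

# Cap histogram bins at 2x the mean bin height (skimage's normalized units),
# tiles on an 8x8 grid.
DEFAULT_CLIP_LIMIT = 2.0 / 256.0
DEFAULT_TILE_GRID: Tuple[int, int] = (8, 8)

_EPS = 1e-12


@dataclass(frozen=True)
class HsiImage:
    """Hue in degrees [0, 360), saturation and intensity in [0, 1]."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hue.shape == self.saturation.shape == self.intensity.shape):
            raise ValueError("HSI channels must share one shape")


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {arr.shape}")
    return arr


def rgb_to_hsi(image: np.ndarray) -> HsiImage:
    """Convert an RGB image (values in [0, 255]) to HSI.

    Uses the arccos formulation: I = (R+G+B)/3, S = 1 - min(R,G,B)/I, and
    H from the angle between the pixel's chromatic component and the red
    axis. Degenerate pixels follow the conventions S=0 where I=0 and H=0
    where the chromatic denominator vanishes (achromatic pixels).
    """
    rgb = _as_float_rgb(image) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    intensity = (r + g + b) / 3.0
    minc = np.minimum(np.minimum(r, g), b)
    saturation = np.where(intensity > _EPS, 1.0 - minc / np.maximum(intensity, _EPS), 0.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = np.degrees(np.arccos(np.clip(num / np.maximum(den, _EPS), -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(den <= _EPS, 0.0, hue)
    return HsiImage(hue=hue, saturation=saturation, intensity=intensity)


def hsi_to_rgb(hsi: HsiImage) -> np.ndarray:
    """Inverse HSI transform; returns a float64 RGB image in [0, 255]."""
    h = np.mod(np.asarray(hsi.hue, dtype=np.float64), 360.0)
    s = np.clip(np.asarray(hsi.saturation, dtype=np.float64), 0.0, 1.0)
    i = np.clip(np.asarray(hsi.intensity, dtype=np.float64), 0.0, 1.0)

    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)

    def _sector(hh):
        """Primary/secondary channel values for a sector-local hue in [0,120)."""
        hr = np.radians(hh)
        first = i * (1.0 - s)
        second = i * (1.0 + s * np.cos(hr) / np.maximum(np.cos(np.radians(60.0) - hr), _EPS))
        third = 3.0 * i - (first + second)
        return first, second, third

    sector0 = h < 120.0
    sector1 = (h >= 120.0) & (h < 240.0)
    sector2 = h >= 240.0

    f, sec, th = _sector(h)
    b = np.where(sector0, f, b)
    r = np.where(sector0, sec, r)
    g = np.where(sector0, th, g)

    f, sec, th = _sector(h - 120.0)
    r = np.where(sector1, f, r)
    g = np.where(sector1, sec, g)
    b = np.where(sector1, th, b)

    f, sec, th = _sector(h - 240.0)
    g = np.where(sector2, f, g)
    b = np.where(sector2, sec, b)
    r = np.where(sector2, th, r)

    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(rgb * 255.0, 0.0, 255.0)


def enhance_illumination(
    image: np.ndarray,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tile_grid: Tuple[int, int] = DEFAULT_TILE_GRID,
) -> np.ndarray:
    """Log + CLAHE enhancement of the intensity channel.

    Pipeline: RGB -> HSI; I' = log(1 + 255*I) / log(256); CLAHE(I') with the
    given clip limit and tile grid; recombine (H, S, I'') and invert back to
    RGB. Hue and saturation are untouched, so the enhancement never shifts
    colors, only local brightness and contrast. Returns float64 in [0, 255]
    with the input's dimensions.
    """
    hsi = rgb_to_hsi(image)
    i_log = np.log1p(255.0 * hsi.intensity) / np.log(256.0)
    h_img, w_img = i_log.shape
    kernel = (max(h_img // tile_grid[0], 1), max(w_img // tile_grid[1], 1))
    i_eq = exposure.equalize_adapthist(i_log, kernel_size=kernel, clip_limit=clip_limit)
    return hsi_to_rgb(HsiImage(hue=hsi.hue, saturation=hsi.saturation, intensity=i_eq))


def resize_bicubic(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bicubic per-channel resize to ``width x height``, clamped to [0, 255].

    Preserves the input dtype (uint8 stays uint8, rounded). Resizing to the
    current dimensions returns an identical copy.
    """
    if width < 1 or height < 1:
        raise ValueError("target dimensions must be >= 1")
    arr = np.asarray(image)
    if arr.shape[0] == height and arr.shape[1] == width:
        return arr.copy()
    out = transform.resize(
        arr.astype(np.float64),
        (height, width) + arr.shape[2:],
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    out = np.clip(out, 0.0, 255.0)
    if arr.dtype == np.uint8:
        return np.rint(out).astype(np.uint8)
    return out
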