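"""Histograms of Oriented Gradients with the detector's tuned geometry.

The descriptor uses 4x8-pixel cells (4 wide, 8 tall), 2x2-cell blocks with a
1-cell stride, and 10 unsigned orientation bins over [0, 180). Gradients are
centered differences ([-1, 0, 1]) with replicated borders; each pixel votes
its gradient magnitude into the two orientation bins adjacent to its
orientation (bilinear voting with circular wrap); blocks are L2-normalized
with an additive epsilon and concatenated row-major.

For a 64x64 window this yields 16x8 cells, 15x7 block positions and a
15*7*4*10 = 4200-dimensional descriptor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "HogConfig",
    "GradientField",
    "compute_gradients",
    "hog_descriptor",
    "hog_descriptor_batch",
    "descriptor_length",
    "to_grayscale",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HogConfig:
    """Descriptor geometry. ``cell`` and ``block`` are (width, height)-ordered;
    cell dimensions in pixels, block dimensions in cells, stride in cells."""

    cell: Tuple[int, int] = (4, 8)
    block: Tuple[int, int] = (2, 2)
    bins: int = 10
    block_stride: int = 1
    epsilon: float = 1e-5
    grayscale_mode: str = "luma"  # or "max"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.block_stride < 1:
            raise ValueError("block_stride must be >= 1")
        if self.grayscale_mode not in ("luma", "max"):
            raise ValueError("grayscale_mode must be 'luma' or 'max'")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "cell": list(self.cell),
                "block": list(self.block),
                "bins": self.bins,
                "stride": self.block_stride,
                "epsilon": self.epsilon,
                "gray": self.grayscale_mode,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def grid_shape(self, width: int, height: int) -> Tuple[int, int]:
        """(n_cells_x, n_cells_y) for a window; raises if incompatible."""
        cw, ch = self.cell
        if width % cw or height % ch:
            raise ValueError(
                f"window {width}x{height} not divisible by cell {cw}x{ch}"
            )
        ncx, ncy = width // cw, height // ch
        bw, bh = self.block
        if ncx < bw or ncy < bh:
            raise ValueError("block does not fit in the cell grid")
        return ncx, ncy


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient magnitude and unsigned orientation in [0, 180)."""

    magnitude: np.ndarray
    orientation: np.ndarray


def to_grayscale(patch: np.ndarray, mode: str = "luma") -> np.ndarray:
    """Collapse an RGB patch to one channel; grayscale input passes through."""
    arr = np.asarray(patch, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        if mode == "luma":
            return arr @ _LUMA
        return arr.max(axis=2)
    raise ValueError(f"expected 2-D or (H, W, 3) patch, got shape {arr.shape}")


def _gradients_batch(gray: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Centered-difference gradients with replicated borders, batched (N,H,W)."""
    padded = np.pad(gray, ((0, 0), (1, 1), (1, 1)), mode="edge")
    gx = padded[:, 1:-1, 2:] - padded[:, 1:-1, :-2]
    gy = padded[:, 2:, 1:-1] - padded[:, :-2, 1:-1]
    mag = np.hypot(gx, gy)
    ang = np.mod(np.degrees(np.arctan2(gy, gx)), 180.0)
    return mag, ang


def compute_gradients(patch: np.ndarray) -> GradientField:
    """Gradient field of a grayscale patch (>= 3x3)."""
    gray = np.asarray(patch, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("compute_gradients expects a 2-D grayscale patch")
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("patch must be at least 3x3")
    mag, ang = _gradients_batch(gray[None])
    return GradientField(magnitude=mag[0], orientation=ang[0])


def descriptor_length(config: HogConfig, width: int = 64, height: int = 64) -> int:
    ncx, ncy = config.grid_shape(width, height)
    bw, bh = config.block
    s = config.block_stride
    nbx = (ncx - bw) // s + 1
    nby = (ncy - bh) // s + 1
    return nbx * nby * bw * bh * config.bins


def hog_descriptor_batch(patches: np.ndarray, config: HogConfig = HogConfig()) -> np.ndarray:
    """Descriptors for a stack of grayscale patches, shape (N, H, W) -> (N, L).

    The batch path is what the scanner uses; a single-patch call goes through
    the same code, so the two are identical by construction.
    """
    gray = np.asarray(patches, dtype=np.float64)
    if gray.ndim != 3:
        raise ValueError("expected (N, H, W) grayscale stack")
    n, h, w = gray.shape
    ncx, ncy = config.grid_shape(w, h)
    cw, ch = config.cell
    bins = config.bins

    mag, ang = _gradients_batch(gray)

    # Bilinear orientation voting with circular wrap on [0, 180).
    bin_width = 180.0 / bins
    pos = ang / bin_width - 0.5
    lower = np.floor(pos)
    frac = pos - lower
    b0 = lower.astype(np.int64) % bins
    b1 = (b0 + 1) % bins
    w0 = mag * (1.0 - frac)
    w1 = mag * frac

    # Accumulate cell histograms with one bincount per vote layer.
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cell_idx = (ys // ch) * ncx + (xs // cw)  # (h, w), row-major cells
    patch_off = (np.arange(n)[:, None, None] * (ncy * ncx) + cell_idx) * bins
    minlength = n * ncy * ncx * bins
    hist = np.bincount((patch_off + b0).ravel(), weights=w0.ravel(), minlength=minlength)
    hist += np.bincount((patch_off + b1).ravel(), weights=w1.ravel(), minlength=minlength)
    hist = hist.reshape(n, ncy, ncx, bins)

    # Blocks: sliding 2x2-cell windows with the configured stride.
    bw, bh = config.block
    s = config.block_stride
    blocks = sliding_window_view(hist, (bh, bw), axis=(1, 2))[:, ::s, ::s]
    # -> (n, nby, nbx, bins, bh, bw); reorder to cells-row-major-then-bins.
    blocks = np.ascontiguousarray(blocks.transpose(0, 1, 2, 4, 5, 3))
    nby, nbx = blocks.shape[1], blocks.shape[2]
    blocks = blocks.reshape(n, nby, nbx, bh * bw * bins)

    norms = np.sqrt(np.sum(blocks**2, axis=-1, keepdims=True) + config.epsilon**2)
    blocks = blocks / norms
    return blocks.reshape(n, nby * nbx * bh * bw * bins)


def hog_descriptor(patch: np.ndarray, config: HogConfig = HogConfig()) -> np.ndarray:
    """Descriptor for one patch (RGB or grayscale); returns a flat vector."""
    gray = to_grayscale(patch, config.grayscale_mode)
    return hog_descriptor_batch(gray[None], config)[0]
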