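"""Bounding boxes, overlap measures, and non-maximum suppression.

Detections emitted by the sliding-window scanner are merged greedily: after
discarding low-confidence boxes, the highest-confidence box is kept and every
remaining box overlapping it by more than the overlap threshold is suppressed.
The default thresholds (overlap 0.3, confidence 0.7) are the operating point
of the detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

__all__ = [
    "BoundingBox",
    "Detection",
    "iou",
    "intersection_over_min",
    "nms",
    "inscribed_circle",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with 0-based top-left corner and half-open extent.

    The box covers pixels ``[x, x+w) x [y, y+h)``; x grows rightward and
    y downward.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box sides must be positive, got {self.w}x{self.h}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> Tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def intersection_area(self, other: "BoundingBox") -> int:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        if iw <= 0 or ih <= 0:
            return 0
        return iw * ih

    def intersects(self, other: "BoundingBox") -> bool:
        return self.intersection_area(other) > 0

    def contains_point(self, px: float, py: float) -> bool:
        return self.x <= px < self.x2 and self.y <= py < self.y2

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox":
        return cls(int(d["x"]), int(d["y"]), int(d["w"]), int(d["h"]))


@dataclass(frozen=True)
class Detection:
    """A candidate object: a box plus a calibrated confidence in [0, 1]."""

    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")

    def to_dict(self) -> dict:
        d = self.box.to_dict()
        d["confidence"] = float(self.confidence)
        (cx, cy), r = inscribed_circle(self.box)
        d["circle"] = {"cx": cx, "cy": cy, "r": r}
        return d


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes."""
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    return inter / float(a.area + b.area - inter)


def intersection_over_min(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area divided by the smaller box's area."""
    return a.intersection_area(b) / float(min(a.area, b.area))


_OVERLAP_MEASURES = {"iou": iou, "min": intersection_over_min}


def _sort_key(det: Detection):
    # Confidence descending, then larger area, then top-left lexicographic:
    # makes the greedy pass independent of input order.
    return (-det.confidence, -det.box.area, det.box.x, det.box.y)


def nms(
    detections: Iterable[Detection],
    overlap_threshold: float = 0.3,
    confidence_threshold: float = 0.7,
    overlap_measure: str = "iou",
) -> List[Detection]:
    """Greedy non-maximum suppression.

    Detections below ``confidence_threshold`` are dropped first. The
    suppression condition is strict (``overlap > overlap_threshold``), so
    boxes overlapping by exactly the threshold both survive.
    """
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must be in [0,1]")
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must be in [0,1]")
    measure = _OVERLAP_MEASURES[overlap_measure]

    pool = sorted(
        (d for d in detections if d.confidence >= confidence_threshold),
        key=_sort_key,
    )
    kept: List[Detection] = []
    while pool:
        best = pool.pop(0)
        kept.append(best)
        pool = [d for d in pool if measure(best.box, d.box) <= overlap_threshold]
    return kept


def inscribed_circle(box: BoundingBox) -> Tuple[Tuple[float, float], float]:
    """Circle centered in the box with radius half the shorter side."""
    return box.center, min(box.w, box.h) / 2.0
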