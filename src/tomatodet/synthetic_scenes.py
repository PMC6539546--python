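"""Synthetic greenhouse scenes with exact ground truth.

Real greenhouse photographs show red, quasi-circular tomatoes on green
foliage under varying light — separated fruit, mutually overlapping fruit,
and fruit partly hidden by leaves. This module renders such scenes at the
detector's working resolution (360x202 by default) so the whole pipeline is
testable without any downloaded imagery, and crops/augments 64x64 training
patches from them.

The rendering model: elliptical leaf blobs in green hues (G > R) over a green
base, fruit as shaded red discs (radial falloff to 70% at the rim, a specular
highlight, +/-10% per-channel hue jitter), optional leaf occluders drawn over
fruit, occasional unripe (green-turning) companion fruit adjacent to ripe
ones — same shape, wrong color, not targets — and a multiplicative
illumination field (sunny / shaded / gradient).
Generation is a pure function of the :class:`SceneSpec`: the same spec gives
a bit-identical scene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from skimage import draw, transform

from .nms import BoundingBox
from .preprocess import resize_bicubic

__all__ = [
    "SceneSpec",
    "SceneAnnotation",
    "SamplePatch",
    "generate_scene",
    "crop_training_samples",
    "augment_rotations",
    "default_training_specs",
    "default_test_specs",
    "annotation_to_dict",
    "annotation_from_dict",
]

FRUIT_BASE_RGB = (200.0, 45.0, 40.0)
UNRIPE_BASE_RGB = (110.0, 150.0, 80.0)
ILLUMINATIONS = ("sunny", "shaded", "gradient")
CONDITIONS = ("separated", "overlapped", "occluded")


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one scene deterministically."""

    width: int = 360
    height: int = 202
    n_tomatoes: int = 2
    radius_range: Tuple[int, int] = (28, 40)
    overlap_fraction: float = 0.0
    occlusion_fraction: float = 0.0
    unripe_fraction: float = 0.25
    illumination: str = "sunny"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("scene must be at least 64x64")
        if not (0.0 <= self.overlap_fraction < 1.0 and 0.0 <= self.occlusion_fraction < 1.0):
            raise ValueError("overlap/occlusion fractions must be in [0, 1)")
        if not 0.0 <= self.unripe_fraction <= 1.0:
            raise ValueError("unripe_fraction must be in [0, 1]")
        if self.illumination not in ILLUMINATIONS:
            raise ValueError(f"illumination must be one of {ILLUMINATIONS}")
        if self.n_tomatoes < 0:
            raise ValueError("n_tomatoes must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid radius_range")


@dataclass
class SceneAnnotation:
    """Exact ground truth for a rendered scene.

    ``fruit_mask`` labels the *visible* pixels of annotated fruit i with
    value i+1 (0 = background); values above ``len(boxes)`` mark unripe
    companion fruit, which are rendered but are not detection targets. The
    mask is kept in memory for tests and patch cropping but is not
    serialized.
    """

    boxes: List[BoundingBox]
    condition_labels: List[str]
    occluded_area: List[float]
    illumination: str = "sunny"
    fruit_mask: Optional[np.ndarray] = None


@dataclass
class SamplePatch:
    """A 64x64 RGB training patch labeled +1 (tomato) or -1 (background)."""

    pixels: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.pixels.shape != (64, 64, 3):
            raise ValueError(f"patch must be 64x64x3, got {self.pixels.shape}")
        if self.label not in (1, -1):
            raise ValueError("label must be +1 or -1")


# ---------------------------------------------------------------------------
# rendering helpers

def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two discs with radii r1, r2 at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    a3 = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - a3


def _overlap_distance(r1: float, r2: float, fraction: float) -> float:
    """Center distance at which lens area / smaller-disc area == fraction."""
    target = fraction * np.pi * min(r1, r2) ** 2

    def err(d):
        return _lens_area(d, r1, r2) - target

    return brentq(err, abs(r1 - r2) + 1e-9, r1 + r2 - 1e-9, xtol=1e-6)


def _paint_background(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    img = np.empty((height, width, 3), dtype=np.float64)
    img[..., 0] = 38.0
    img[..., 1] = 92.0
    img[..., 2] = 36.0
    n_leaves = max(12, width * height // 1500)
    for _ in range(n_leaves):
        cy = rng.uniform(0, height)
        cx = rng.uniform(0, width)
        a = rng.uniform(8, 30)   # semi-major
        b = rng.uniform(5, 18)   # semi-minor
        angle = rng.uniform(0, np.pi)
        g = rng.uniform(70, 170)
        color = np.array([rng.uniform(0.2, 0.6) * g, g, rng.uniform(0.2, 0.55) * g])
        rr, cc = draw.ellipse(cy, cx, b, a, shape=(height, width), rotation=angle)
        img[rr, cc] = color
    img += rng.normal(0.0, 5.0, img.shape)
    return np.clip(img, 0.0, 255.0)


def _render_fruit(
    img: np.ndarray,
    rng: np.random.Generator,
    cx: int,
    cy: int,
    r: int,
    base_rgb: Tuple[float, float, float] = FRUIT_BASE_RGB,
) -> np.ndarray:
    """Draw one shaded fruit disc; returns its boolean geometric mask."""
    h, w = img.shape[:2]
    yy, xx = np.ogrid[:h, :w]
    dist2 = (xx - cx) ** 2 + (yy - cy) ** 2
    disc = dist2 <= r**2
    rho2 = dist2 / float(r**2)
    shade = 1.0 - 0.3 * rho2
    base = np.array(base_rgb) * (1.0 + rng.uniform(-0.1, 0.1, 3))
    sx, sy = cx - 0.3 * r, cy - 0.3 * r
    spec = 60.0 * np.exp(-((xx - sx) ** 2 + (yy - sy) ** 2) / (2 * (0.18 * r) ** 2))
    for c in range(3):
        channel = np.clip(base[c] * shade + spec, 0.0, 255.0)
        img[..., c] = np.where(disc, channel, img[..., c])
    return disc


def _occluder_mask(
    height: int, width: int, cx: float, cy: float, r: float, angle: float, t: float
) -> Tuple[np.ndarray, np.ndarray]:
    ocx = cx + t * np.cos(angle)
    ocy = cy + t * np.sin(angle)
    rr, cc = draw.ellipse(ocy, ocx, 0.8 * r, 1.1 * r, shape=(height, width),
                          rotation=angle)
    return rr, cc


def _apply_occluder(
    img: np.ndarray,
    fruit_mask: np.ndarray,
    rng: np.random.Generator,
    fruit_id: int,
    cx: int,
    cy: int,
    r: int,
    target: float,
) -> float:
    """Slide a leaf ellipse toward the fruit until it covers ~target of it."""
    h, w = img.shape[:2]
    disc_area = float(np.count_nonzero(fruit_mask == fruit_id))
    if disc_area == 0:
        return 0.0
    angle = rng.uniform(0, 2 * np.pi)

    def covered(t: float) -> float:
        rr, cc = _occluder_mask(h, w, cx, cy, r, angle, t)
        hit = np.zeros((h, w), dtype=bool)
        hit[rr, cc] = True
        return np.count_nonzero(hit & (fruit_mask == fruit_id)) / disc_area

    lo, hi = 0.0, 2.4 * r  # covered() decreases from ~max to 0 over [lo, hi]
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if covered(mid) > target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    rr, cc = _occluder_mask(h, w, cx, cy, r, angle, t)
    g = rng.uniform(95, 150)
    color = np.array([0.35 * g, g, 0.3 * g])
    img[rr, cc] = color + rng.normal(0.0, 4.0, (len(rr), 3))
    np.clip(img, 0.0, 255.0, out=img)
    frac_before = covered(t)
    hit = np.zeros((h, w), dtype=bool)
    hit[rr, cc] = True
    fruit_mask[hit] = 0
    return frac_before


def _illumination_field(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    x = np.linspace(0.0, 1.0, spec.width)[None, :]
    ramp = np.broadcast_to(x, (spec.height, spec.width))
    direction = 1.0 if rng.random() < 0.5 else -1.0
    if spec.illumination == "sunny":
        return 1.07 + direction * 0.08 * (ramp - 0.5)
    if spec.illumination == "shaded":
        return 0.65 + direction * 0.05 * (ramp - 0.5)
    return 0.45 + 0.7 * ramp  # strong lighting gradient


# ---------------------------------------------------------------------------
# public operations

def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, SceneAnnotation]:
    """Render a scene; returns a uint8 RGB image and its exact annotation.

    Fruit are placed so that requested pairwise overlap (fraction of the
    smaller disc's area) is met geometrically; occlusion is realized by
    drawing a leaf ellipse over the fruit and measuring the covered fraction
    by pixel counting. Raises ``RuntimeError`` when placement is infeasible
    after bounded retries.
    """
    rng = np.random.default_rng(spec.rng_seed)
    w, h = spec.width, spec.height
    img = _paint_background(rng, w, h)

    radii = [int(round(r)) for r in rng.uniform(*spec.radius_range, spec.n_tomatoes)]
    if 2 * sum(np.pi * r**2 for r in radii) > w * h:
        raise RuntimeError("infeasible placement: fruit area exceeds half the scene")

    # group fruit into overlapping pairs when overlap is requested
    pair_of = {}
    if spec.overlap_fraction > 0:
        for i in range(0, spec.n_tomatoes - 1, 2):
            pair_of[i] = i + 1
            pair_of[i + 1] = i

    centers: List[Tuple[int, int]] = []
    boxes: List[BoundingBox] = []

    def _bbox(cx: int, cy: int, r: int) -> BoundingBox:
        return BoundingBox(cx - r, cy - r, 2 * r + 1, 2 * r + 1)

    def _fits(cx: int, cy: int, r: int, ignore: Sequence[int]) -> bool:
        if not (r + 1 <= cx < w - r - 1 and r + 1 <= cy < h - r - 1):
            return False
        cand = _bbox(cx, cy, r)
        return all(
            not cand.intersects(b) for j, b in enumerate(boxes) if j not in ignore
        )

    i = 0
    while i < spec.n_tomatoes:
        r = radii[i]
        partner = pair_of.get(i)
        placed = False
        for _ in range(300):
            cx = int(rng.integers(r + 1, w - r - 1))
            cy = int(rng.integers(r + 1, h - r - 1))
            if not _fits(cx, cy, r, ignore=()):
                continue
            if partner is not None and partner == i + 1:
                r2 = radii[partner]
                d = _overlap_distance(r, r2, spec.overlap_fraction)
                ok = False
                for _ in range(60):
                    theta = rng.uniform(0, 2 * np.pi)
                    px = int(round(cx + d * np.cos(theta)))
                    py = int(round(cy + d * np.sin(theta)))
                    if _fits(px, py, r2, ignore=(len(boxes),)):
                        ok = True
                        break
                if not ok:
                    continue
                centers.append((cx, cy))
                boxes.append(_bbox(cx, cy, r))
                centers.append((px, py))
                boxes.append(_bbox(px, py, r2))
                i += 2
            else:
                centers.append((cx, cy))
                boxes.append(_bbox(cx, cy, r))
                i += 1
            placed = True
            break
        if not placed:
            raise RuntimeError("infeasible placement: retries exhausted")

    fruit_mask = np.zeros((h, w), dtype=np.int32)
    for idx, ((cx, cy), r) in enumerate(zip(centers, radii)):
        disc = _render_fruit(img, rng, cx, cy, r)
        fruit_mask[disc] = idx + 1

    occluded = [0.0] * spec.n_tomatoes
    if spec.occlusion_fraction > 0:
        for idx in range(spec.n_tomatoes):
            if idx in pair_of:
                continue  # occlusion is applied to unpaired fruit only
            cx, cy = centers[idx]
            occluded[idx] = _apply_occluder(
                img, fruit_mask, rng, idx + 1, cx, cy, radii[idx],
                spec.occlusion_fraction,
            )

    # Unripe companion fruit: greenhouse trusses carry immature green/turning
    # tomatoes next to ripe ones. They share the ripe fruit's shaded-sphere
    # geometry but not its color, are never annotated as targets, and get
    # mask ids above n_tomatoes.
    n_companions = 0
    for idx in range(spec.n_tomatoes):
        if rng.random() >= spec.unripe_fraction:
            continue
        cx, cy = centers[idx]
        r2 = int(round(0.9 * rng.uniform(*spec.radius_range)))
        for _ in range(40):
            theta = rng.uniform(0, 2 * np.pi)
            d = radii[idx] + r2 + 2
            px = int(round(cx + d * np.cos(theta)))
            py = int(round(cy + d * np.sin(theta)))
            cand = _bbox(px, py, r2)
            if not (r2 + 1 <= px < w - r2 - 1 and r2 + 1 <= py < h - r2 - 1):
                continue
            if any(cand.intersects(b) for b in boxes):
                continue
            disc = _render_fruit(img, rng, px, py, r2, base_rgb=UNRIPE_BASE_RGB)
            n_companions += 1
            fruit_mask[disc] = spec.n_tomatoes + n_companions
            break

    img *= _illumination_field(spec, rng)[..., None]
    img = np.clip(img, 0.0, 255.0)
    image = np.rint(img).astype(np.uint8)

    labels = []
    for idx, box in enumerate(boxes):
        if occluded[idx] > 1e-3:
            labels.append("occluded")
        elif any(box.intersects(b) for j, b in enumerate(boxes) if j != idx):
            labels.append("overlapped")
        else:
            labels.append("separated")

    annotation = SceneAnnotation(
        boxes=boxes,
        condition_labels=labels,
        occluded_area=occluded,
        illumination=spec.illumination,
        fruit_mask=fruit_mask,
    )
    return image, annotation


def crop_training_samples(
    image: np.ndarray,
    annotation: SceneAnnotation,
    n_background: int,
    margin: int = 5,
    margin_jitter: int = 3,
    rng_seed: int = 0,
) -> List[SamplePatch]:
    """Crop one positive patch per fruit and random background patches.

    Positives are the ground-truth boxes expanded by about ``margin`` pixels
    per side (each side jittered independently by up to ``margin_jitter``,
    emulating the imprecision of manual cropping) and resized to 64x64.
    Backgrounds are windows (random side 48-96 px) whose fruit-pixel coverage
    is below 20%, also resized to 64x64. If too few clean background windows
    exist, as many as possible are returned with a warning.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = image.shape[:2]
    patches: List[SamplePatch] = []
    for box in annotation.boxes:
        m0, m1, m2, m3 = (
            max(0, margin + int(rng.integers(-margin_jitter, margin_jitter + 1)))
            for _ in range(4)
        )
        x0 = max(0, box.x - m0)
        y0 = max(0, box.y - m1)
        x1 = min(w, box.x2 + m2)
        y1 = min(h, box.y2 + m3)
        crop = image[y0:y1, x0:x1]
        patches.append(SamplePatch(resize_bicubic(crop, 64, 64), 1))

    if annotation.fruit_mask is not None:
        fruit = annotation.fruit_mask > 0
    else:
        fruit = np.zeros((h, w), dtype=bool)
        for box in annotation.boxes:
            fruit[box.y:box.y2, box.x:box.x2] = True

    found = 0
    for _ in range(60 * max(1, n_background)):
        if found >= n_background:
            break
        side = int(rng.integers(48, 97))
        if side > min(w, h):
            side = min(w, h)
        x = int(rng.integers(0, w - side + 1))
        y = int(rng.integers(0, h - side + 1))
        window = fruit[y:y + side, x:x + side]
        if window.mean() >= 0.2:
            continue
        crop = image[y:y + side, x:x + side]
        patches.append(SamplePatch(resize_bicubic(crop, 64, 64), -1))
        found += 1
    if found < n_background:
        warnings.warn(
            f"only {found}/{n_background} background patches found", stacklevel=2
        )
    return patches


def rotate_patch(pixels: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a patch about its center, filling edges by reflection.

    An angle that is a multiple of 360 degrees returns an exact copy.
    """
    if angle % 360.0 == 0.0:
        return pixels.copy()
    out = transform.rotate(
        pixels.astype(np.float64), angle, mode="symmetric",
        order=1, preserve_range=True,
    )
    out = np.clip(out, 0.0, 255.0)
    if pixels.dtype == np.uint8:
        out = np.rint(out).astype(np.uint8)
    return out


def augment_rotations(patches: Sequence[SamplePatch], rng_seed: int = 0) -> List[SamplePatch]:
    """Append one randomly rotated copy (0-360 deg) of every patch.

    Rotation is about the patch center with edge pixels filled by reflection;
    output order is all originals followed by their rotated copies, so the
    result has exactly twice the input length and preserves labels.
    """
    if not patches:
        raise ValueError("augment_rotations needs a non-empty patch list")
    rng = np.random.default_rng(rng_seed)
    rotated = [
        SamplePatch(rotate_patch(p.pixels, float(rng.uniform(0.0, 360.0))), p.label)
        for p in patches
    ]
    return list(patches) + rotated


# ---------------------------------------------------------------------------
# standard dataset layouts

def default_training_specs(seed: int, n_scenes: int = 69, fruit_per_scene: int = 3) -> List[SceneSpec]:
    """Training scenes mixing the three growing conditions, sunny/shaded.

    Training imagery shows the same population as the test imagery —
    separated, overlapping, and leaf-occluded fruit — in roughly the field
    proportions (10:40:25), with illumination alternating scene by scene.
    The default 69 scenes x 3 fruit yield 207 positive patches; with three
    background crops per fruit and rotation augmentation this gives the
    canonical 1656-sample training set (207 + 621, doubled).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, n_scenes)
    n_sep = max(1, round(n_scenes * 10 / 75))
    n_ovl = max(1, round(n_scenes * 40 / 75))
    specs = []
    for i in range(n_scenes):
        if i < n_sep:
            overlap, occl = 0.0, 0.0
        elif i < n_sep + n_ovl:
            overlap, occl = float(rng.uniform(0.15, 0.35)), 0.0
        else:
            overlap, occl = 0.0, float(rng.uniform(0.15, 0.35))
        specs.append(
            SceneSpec(
                n_tomatoes=fruit_per_scene,
                overlap_fraction=overlap,
                occlusion_fraction=occl,
                illumination="sunny" if i % 2 == 0 else "shaded",
                rng_seed=int(seeds[i]),
            )
        )
    return specs


def default_test_specs(seed: int, n_scenes: int = 75) -> List[SceneSpec]:
    """Test scenes: 2 fruit each, mixing the three growing conditions.

    The 75-scene default splits into 10 separated / 40 overlapped / 25
    occluded scenes (20 / 80 / 50 fruit, close to the field proportions of a
    greenhouse test set) with illumination alternating sunny/shaded.
    Overlap and occlusion fractions are drawn from [0.15, 0.35].
    """
    rng = np.random.default_rng(seed + 1)
    seeds = rng.integers(0, 2**31 - 1, n_scenes)
    n_sep = max(1, round(n_scenes * 10 / 75))
    n_ovl = max(1, round(n_scenes * 40 / 75))
    specs = []
    for i in range(n_scenes):
        if i < n_sep:
            overlap, occl = 0.0, 0.0
        elif i < n_sep + n_ovl:
            overlap, occl = float(rng.uniform(0.15, 0.35)), 0.0
        else:
            overlap, occl = 0.0, float(rng.uniform(0.15, 0.35))
        specs.append(
            SceneSpec(
                n_tomatoes=2,
                overlap_fraction=overlap,
                occlusion_fraction=occl,
                illumination="sunny" if i % 2 == 0 else "shaded",
                rng_seed=int(seeds[i]),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# serialization

def annotation_to_dict(annotation: SceneAnnotation, spec: Optional[SceneSpec] = None) -> dict:
    d = {
        "boxes": [
            {**box.to_dict(), "condition": cond, "occluded_area": float(occ)}
            for box, cond, occ in zip(
                annotation.boxes, annotation.condition_labels, annotation.occluded_area
            )
        ],
        "illumination": annotation.illumination,
    }
    if spec is not None:
        d["spec"] = asdict(spec)
    return d


def annotation_from_dict(d: dict) -> SceneAnnotation:
    boxes = [BoundingBox.from_dict(b) for b in d["boxes"]]
    return SceneAnnotation(
        boxes=boxes,
        condition_labels=[b["condition"] for b in d["boxes"]],
        occluded_area=[float(b["occluded_area"]) for b in d["boxes"]],
        illumination=d.get("illumination", "sunny"),
    )
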