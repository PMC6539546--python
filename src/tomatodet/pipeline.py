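"""End-to-end orchestration: configuration, training, detection, experiment.

The detector runs enhance -> Naive-Bayes ROI -> pyramid sliding-window HOG +
SVM -> False Color Removal -> NMS. This module wires the stage modules
together behind one configuration object whose defaults are the tuned
operating point of the detector, trains the two models from synthetic
scenes, and persists/loads model bundles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import evaluation, linear_svm, roi_extraction, synthetic_scenes
from .fcr import ColorPlane, FcrConfig, DEFAULT_PLANE
from .hog_features import HogConfig, hog_descriptor_batch, to_grayscale
from .linear_svm import LinearModel
from .nms import Detection, nms
from .preprocess import enhance_illumination, DEFAULT_CLIP_LIMIT, DEFAULT_TILE_GRID
from .roi_extraction import NBModel
from .scanner import PyramidSpec, WindowSpec, scan
from .synthetic_scenes import SceneAnnotation, SceneSpec, SamplePatch

__all__ = [
    "PipelineConfig",
    "TrainedModels",
    "train_models",
    "detect_scene",
    "run_experiment",
    "save_models",
    "load_models",
]


@dataclass(frozen=True)
class PreprocessConfig:
    clip_limit: float = DEFAULT_CLIP_LIMIT
    tile_grid: Tuple[int, int] = DEFAULT_TILE_GRID
    resize_width: int = 360
    resize_height: int = 202


@dataclass(frozen=True)
class SvmTrainConfig:
    C: float = 1.0
    tol: float = 1e-4
    calibration_frac: float = 0.25


@dataclass(frozen=True)
class RoiConfig:
    pad: int = 16
    min_area: int = 25
    footprint_size: int = 3


@dataclass(frozen=True)
class NmsConfig:
    overlap_threshold: float = 0.3
    confidence_threshold: float = 0.7
    overlap_measure: str = "iou"


@dataclass(frozen=True)
class EvalConfig:
    min_iou: float = 0.5
    criterion: str = "iou"


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = PreprocessConfig()
    hog: HogConfig = HogConfig()
    svm: SvmTrainConfig = SvmTrainConfig()
    roi: RoiConfig = RoiConfig()
    pyramid: PyramidSpec = PyramidSpec()
    window: WindowSpec = WindowSpec()
    fcr: FcrConfig = FcrConfig()
    nms: NmsConfig = NmsConfig()
    evaluation: EvalConfig = EvalConfig()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fcr"] = {
            "plane": self.fcr.plane.to_dict(),
            "binarize_threshold": self.fcr.binarize_threshold,
            "ratio_threshold": self.fcr.ratio_threshold,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def sub(section, klass, **converted):
            kwargs = dict(d.get(section, {}))
            kwargs.update(converted)
            for k, v in list(kwargs.items()):
                if isinstance(v, list):
                    kwargs[k] = tuple(v)
            return klass(**kwargs)

        fcr_d = dict(d.get("fcr", {}))
        if "plane" in fcr_d:
            fcr_d["plane"] = ColorPlane.from_dict(fcr_d["plane"])
        return cls(
            preprocess=sub("preprocess", PreprocessConfig),
            hog=sub("hog", HogConfig),
            svm=sub("svm", SvmTrainConfig),
            roi=sub("roi", RoiConfig),
            pyramid=sub("pyramid", PyramidSpec),
            window=sub("window", WindowSpec),
            fcr=FcrConfig(**fcr_d),
            nms=sub("nms", NmsConfig),
            evaluation=sub("evaluation", EvalConfig),
        )


@dataclass
class TrainedModels:
    svm: LinearModel
    nb: NBModel
    training_report: Optional[dict] = None


def _enhanced_uint8(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    out = enhance_illumination(image, cfg.clip_limit, cfg.tile_grid)
    return np.rint(out).astype(np.uint8)


# offsets of a radius-18 disc around the 64x64 patch center: safely inside
# the fruit for positive patches cropped with a 5 px margin
_yy, _xx = np.mgrid[:64, :64]
_CENTER_DISC = (_xx - 32) ** 2 + (_yy - 32) ** 2 <= 18**2
del _yy, _xx


def _nb_training_pixels(
    patches: Sequence[SamplePatch], rng: np.random.Generator, per_patch: int = 60
) -> Tuple[np.ndarray, np.ndarray]:
    pixels, labels = [], []
    centre_idx = np.flatnonzero(_CENTER_DISC.ravel())
    for patch in patches:
        flat = patch.pixels.reshape(-1, 3)
        if patch.label == 1:
            chosen = rng.choice(centre_idx, size=per_patch, replace=False)
        else:
            chosen = rng.choice(flat.shape[0], size=per_patch, replace=False)
        pixels.append(flat[chosen])
        labels.append(np.full(per_patch, patch.label))
    return np.concatenate(pixels), np.concatenate(labels)


def train_models(
    scenes: Sequence[Tuple[np.ndarray, SceneAnnotation]],
    config: PipelineConfig = PipelineConfig(),
    rng_seed: int = 0,
    backgrounds_per_fruit: int = 3,
    augment: bool = True,
) -> TrainedModels:
    """Train the SVM (HOG patches) and pixel NB from annotated scenes.

    Scenes are illumination-enhanced first, patches cropped (one positive per
    fruit, ``backgrounds_per_fruit`` negatives each) and rotation-augmented,
    then HOG descriptors feed the SVM and sampled patch pixels feed the color
    Naive Bayes. The returned bundle carries the training-set confusion
    counts in ``training_report``.
    """
    rng = np.random.default_rng(rng_seed)
    patches: List[SamplePatch] = []
    for image, annotation in scenes:
        enhanced = _enhanced_uint8(image, config.preprocess)
        n_bg = backgrounds_per_fruit * max(1, len(annotation.boxes))
        patches.extend(
            synthetic_scenes.crop_training_samples(
                enhanced, annotation, n_background=n_bg, margin=5,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
        )
    if not patches:
        raise ValueError("no training patches: dataset is empty")

    nb_pixels, nb_labels = _nb_training_pixels(patches, rng)
    nb = roi_extraction.train_nb(
        roi_extraction.pixel_color_features(nb_pixels), nb_labels
    )

    if augment:
        patches = synthetic_scenes.augment_rotations(
            patches, rng_seed=int(rng.integers(2**31 - 1))
        )
    gray = np.stack(
        [to_grayscale(p.pixels, config.hog.grayscale_mode) for p in patches]
    )
    X = hog_descriptor_batch(gray, config.hog)
    y = np.array([p.label for p in patches])
    svm = linear_svm.train(
        X, y, C=config.svm.C, calibrate=True,
        calibration_frac=config.svm.calibration_frac, tol=config.svm.tol,
        rng_seed=int(rng.integers(2**31 - 1)),
    )
    svm.hog_config_hash = config.hog.config_hash()

    pred = linear_svm.predict(svm, X)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    report = {
        "n_samples": len(y),
        "n_positive": int(np.sum(y == 1)),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "recall_pct": evaluation.round_half_up_pct(100.0 * tp / max(1, tp + fn)),
        "precision_pct": evaluation.round_half_up_pct(100.0 * tp / max(1, tp + fp)),
    }
    return TrainedModels(svm=svm, nb=nb, training_report=report)


def detect_scene(
    image: np.ndarray,
    models: TrainedModels,
    config: PipelineConfig = PipelineConfig(),
    use_fcr: bool = True,
    use_roi: bool = True,
    return_debug: bool = False,
):
    """Full detection pipeline on one image; returns merged detections.

    ``use_fcr=False`` is the ablation path without False Color Removal;
    ``use_roi=False`` scans the whole pyramid exhaustively instead of the
    color-pruned regions of interest.
    """
    enhanced = _enhanced_uint8(image, config.preprocess)
    rois = None
    mask = None
    if use_roi:
        mask = roi_extraction.classify_pixels(models.nb, enhanced)
        rois = roi_extraction.extract_roi(
            mask,
            window=config.window.window,
            pad=config.roi.pad,
            min_area=config.roi.min_area,
            footprint_size=config.roi.footprint_size,
        )
    result = scan(
        enhanced,
        models.svm,
        hog_config=config.hog,
        fcr_config=config.fcr if use_fcr else None,
        pyramid=config.pyramid,
        winspec=config.window,
        rois=rois,
        return_debug=return_debug,
    )
    raw, debug = result if return_debug else (result, None)
    detections = nms(
        [Detection(r.box, r.confidence) for r in raw],
        overlap_threshold=config.nms.overlap_threshold,
        confidence_threshold=config.nms.confidence_threshold,
        overlap_measure=config.nms.overlap_measure,
    )
    if return_debug:
        debug["rois"] = [r.to_dict() for r in rois] if rois is not None else None
        debug["roi_area_fraction"] = (
            sum(r.area for r in rois) / float(image.shape[0] * image.shape[1])
            if rois is not None else 1.0
        )
        debug["raw_detections"] = len(raw)
        debug["final_detections"] = len(detections)
        return detections, debug
    return detections


def run_experiment(
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
    n_train_scenes: int = 69,
    n_test_scenes: int = 75,
    with_ablation: bool = True,
) -> dict:
    """Train on synthetic scenes and evaluate detection on a fresh test set.

    Returns overall and per-condition/per-illumination rates for the full
    pipeline and (optionally) the FCR-ablated run, plus the SVM training
    report. All randomness derives from ``seed``.
    """
    train_specs = synthetic_scenes.default_training_specs(seed)[:n_train_scenes]
    train_scenes = [synthetic_scenes.generate_scene(s) for s in train_specs]
    models = train_models(train_scenes, config, rng_seed=seed + 101)

    test_specs = synthetic_scenes.default_test_specs(seed)[:n_test_scenes]
    per_scene_full, per_scene_nofcr = [], []
    for spec in test_specs:
        image, annotation = synthetic_scenes.generate_scene(spec)
        entry = {
            "boxes": annotation.boxes,
            "condition": annotation.condition_labels,
            "illumination": annotation.illumination,
        }
        dets = detect_scene(image, models, config, use_fcr=True)
        per_scene_full.append({**entry, "detections": dets})
        if with_ablation:
            dets_ab = detect_scene(image, models, config, use_fcr=False)
            per_scene_nofcr.append({**entry, "detections": dets_ab})

    def _summarize(per_scene):
        overall = evaluation.evaluate_conditions(
            per_scene, min_iou=config.evaluation.min_iou,
            criterion=config.evaluation.criterion, group_keys=(),
        )
        by_condition = evaluation.evaluate_conditions(
            per_scene, min_iou=config.evaluation.min_iou,
            criterion=config.evaluation.criterion, group_keys=("condition",),
        )
        by_light = evaluation.evaluate_conditions(
            per_scene, min_iou=config.evaluation.min_iou,
            criterion=config.evaluation.criterion, group_keys=("illumination",),
        )
        row = overall[overall.condition == "all"].iloc[0]
        tp, fp, fn = int(row.correct), int(row["false"]), int(row.missed)
        metrics = evaluation.compute_metrics(
            evaluation.MatchResult(tp=tp, fp=fp, fn=fn, assignments=[0] * 0)
        )
        return {
            "metrics": metrics,
            "by_condition": by_condition,
            "by_illumination": by_light,
        }

    result = {
        "models": models,
        "training_report": models.training_report,
        "n_test_scenes": len(test_specs),
        "n_fruit": sum(s.n_tomatoes for s in test_specs),
        "full": _summarize(per_scene_full),
    }
    if with_ablation:
        result["no_fcr"] = _summarize(per_scene_nofcr)
    return result


# ---------------------------------------------------------------------------
# persistence

def save_models(models: TrainedModels, out_dir, config: PipelineConfig = PipelineConfig()) -> None:
    """Write a model bundle: numeric arrays (npz) + JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(
        out / "model_arrays.npz",
        svm_weights=models.svm.weights,
        nb_means=models.nb.means,
        nb_variances=models.nb.variances,
        nb_priors=models.nb.priors,
    )
    meta = {
        "svm": {
            "bias": models.svm.bias,
            "C": models.svm.C,
            "calibration_scale": models.svm.calibration_scale,
            "hog_config_hash": models.svm.hog_config_hash,
        },
        "fcr_plane": config.fcr.plane.to_dict(),
        "config": config.to_dict(),
        "training_report": models.training_report,
    }
    (out / "model_meta.json").write_text(json.dumps(meta, indent=2))


def load_models(model_dir) -> Tuple[TrainedModels, PipelineConfig]:
    model_dir = Path(model_dir)
    arrays = np.load(model_dir / "model_arrays.npz")
    meta = json.loads((model_dir / "model_meta.json").read_text())
    svm = LinearModel(
        weights=arrays["svm_weights"],
        bias=float(meta["svm"]["bias"]),
        C=float(meta["svm"]["C"]),
        calibration_scale=meta["svm"]["calibration_scale"],
        hog_config_hash=meta["svm"]["hog_config_hash"],
    )
    nb = NBModel(
        means=arrays["nb_means"],
        variances=arrays["nb_variances"],
        priors=arrays["nb_priors"],
    )
    config = PipelineConfig.from_dict(meta["config"])
    return TrainedModels(svm=svm, nb=nb, training_report=meta.get("training_report")), config
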