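"""Detection evaluation: ground-truth matching, detection rates, ROC/AUC.

Detections are matched to ground truth greedily in decreasing confidence;
each detection may claim one unclaimed ground-truth box (highest IoU at or
above the matching threshold, 0.5 by default). Duplicate detections on an
already-claimed fruit count as false positives. Rates follow the detection
literature:

    recall    = TP / (TP + FN)        (correct identification rate)
    precision = TP / (TP + FP)
    F1        = 2 * P * R / (P + R)
    false rate  = FP / (TP + FP)
    missed rate = FN / (TP + FN)

all reported as percentages rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .nms import BoundingBox, Detection, iou

__all__ = [
    "MatchResult",
    "MetricsReport",
    "match_detections",
    "compute_metrics",
    "f1_from_rates",
    "roc_auc",
    "evaluate_conditions",
    "round_half_up_pct",
]


def round_half_up_pct(value: float, decimals: int = 2) -> float:
    """Round a percentage half-up (the convention of printed result tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    assignments: List[Optional[int]]  # per detection: matched gt index or None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    fn: int
    recall_pct: float
    precision_pct: float
    f1_pct: float
    false_rate_pct: float
    missed_rate_pct: float


def match_detections(
    detections: Sequence[Detection],
    ground_truths: Sequence[BoundingBox],
    min_iou: float = 0.5,
    criterion: str = "iou",
) -> MatchResult:
    """Greedy confidence-ordered assignment of detections to ground truth.

    ``criterion='iou'`` requires overlap >= ``min_iou``; ``criterion='center'``
    instead accepts a detection whose box center falls inside the ground-truth
    box (ties among eligible boxes still resolved by IoU).
    """
    if criterion not in ("iou", "center"):
        raise ValueError("criterion must be 'iou' or 'center'")
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].confidence, detections[i].box.x, detections[i].box.y),
    )
    claimed = [False] * len(ground_truths)
    assignments: List[Optional[int]] = [None] * len(detections)
    for det_idx in order:
        det = detections[det_idx]
        best_gt, best_overlap = None, 0.0
        for gt_idx, gt in enumerate(ground_truths):
            if claimed[gt_idx]:
                continue
            overlap = iou(det.box, gt)
            if criterion == "iou":
                eligible = overlap >= min_iou
            else:
                eligible = gt.contains_point(*det.box.center)
            if eligible and overlap >= best_overlap and (best_gt is None or overlap > best_overlap):
                best_gt, best_overlap = gt_idx, overlap
        if best_gt is not None:
            claimed[best_gt] = True
            assignments[det_idx] = best_gt
    tp = sum(a is not None for a in assignments)
    return MatchResult(
        tp=tp,
        fp=len(detections) - tp,
        fn=len(ground_truths) - tp,
        assignments=assignments,
    )


def compute_metrics(match: MatchResult) -> MetricsReport:
    """Rates from a match result; requires at least one ground-truth object.

    Precision is defined as 0 when there are no detections, and F1 as 0 when
    precision + recall is 0.
    """
    if match.tp + match.fn == 0:
        raise ValueError("metrics need at least one ground-truth object")
    recall = match.tp / (match.tp + match.fn)
    precision = match.tp / (match.tp + match.fp) if (match.tp + match.fp) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    false_rate = match.fp / (match.tp + match.fp) if (match.tp + match.fp) else 0.0
    missed_rate = match.fn / (match.tp + match.fn)
    return MetricsReport(
        tp=match.tp,
        fp=match.fp,
        fn=match.fn,
        recall_pct=round_half_up_pct(100.0 * recall),
        precision_pct=round_half_up_pct(100.0 * precision),
        f1_pct=round_half_up_pct(100.0 * f1),
        false_rate_pct=round_half_up_pct(100.0 * false_rate),
        missed_rate_pct=round_half_up_pct(100.0 * missed_rate),
    )


def f1_from_rates(recall_pct: float, precision_pct: float) -> float:
    """F1 (percent, 2 decimals) from already-rounded percentage rates."""
    if recall_pct + precision_pct == 0:
        return 0.0
    f1 = 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)
    return round_half_up_pct(f1)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by the rank (Mann-Whitney) formulation, tie-aware."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_conditions(
    per_scene: Sequence[dict],
    min_iou: float = 0.5,
    criterion: str = "iou",
    group_keys: Sequence[str] = ("condition",),
) -> pd.DataFrame:
    """Stratified report over scenes, mirroring per-condition result tables.

    ``per_scene`` entries carry ``detections`` (list of Detection), ``boxes``
    (ground-truth BoundingBox list), per-box ``condition`` labels, and scene
    attributes such as ``illumination``. TPs and FNs are attributed to their
    ground-truth box's group; FPs to the group of their highest-IoU ground
    truth (or the scene's first group if the scene has no ground truth).
    Returns one row per group plus an "all" row with the Table-style columns
    count / correct / correct_rate / false / false_rate / missed / missed_rate.
    """
    counters: Dict[str, Dict[str, int]] = {}

    def _bucket(group: str) -> Dict[str, int]:
        return counters.setdefault(group, {"count": 0, "tp": 0, "fp": 0, "fn": 0})

    for scene in per_scene:
        dets: Sequence[Detection] = scene["detections"]
        gts: Sequence[BoundingBox] = scene["boxes"]
        conds = scene.get("condition") or ["all"] * len(gts)
        groups = [
            "/".join(str(cond) if k == "condition" else str(scene[k]) for k in group_keys)
            for cond in conds
        ]
        match = match_detections(dets, gts, min_iou=min_iou, criterion=criterion)
        matched_gts = set(a for a in match.assignments if a is not None)
        for gt_idx, group in enumerate(groups):
            b = _bucket(group)
            b["count"] += 1
            if gt_idx in matched_gts:
                b["tp"] += 1
            else:
                b["fn"] += 1
        for det_idx, assigned in enumerate(match.assignments):
            if assigned is not None:
                continue
            if gts:
                best = max(range(len(gts)), key=lambda j: iou(dets[det_idx].box, gts[j]))
                group = groups[best]
            else:
                group = "background"
            _bucket(group)["fp"] += 1

    rows = []
    order = sorted(counters)
    total = {"count": 0, "tp": 0, "fp": 0, "fn": 0}
    for group in order:
        c = counters[group]
        for k in total:
            total[k] += c[k]
        rows.append(_report_row(group, c))
    rows.append(_report_row("all", total))
    return pd.DataFrame(rows)


def _report_row(name: str, c: Dict[str, int]) -> dict:
    denom_det = c["tp"] + c["fp"]
    denom_gt = c["tp"] + c["fn"]
    return {
        "condition": name,
        "count": c["count"],
        "correct": c["tp"],
        "correct_rate": round_half_up_pct(100.0 * c["tp"] / denom_gt) if denom_gt else 0.0,
        "false": c["fp"],
        "false_rate": round_half_up_pct(100.0 * c["fp"] / denom_det) if denom_det else 0.0,
        "missed": c["fn"],
        "missed_rate": round_half_up_pct(100.0 * c["fn"] / denom_gt) if denom_gt else 0.0,
    }
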