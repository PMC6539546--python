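import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tomatodet.evaluation import (
    MatchResult,
    compute_metrics,
    evaluate_conditions,
    f1_from_rates,
    match_detections,
    roc_auc,
)
from tomatodet.nms import BoundingBox, Detection

from _oracles import auc_concordance


def _det(x, y, w, h, conf):
    return Detection(BoundingBox(x, y, w, h), conf)


class TestMatchDetections:
    gts = [BoundingBox(0, 0, 50, 50), BoundingBox(100, 0, 50, 50), BoundingBox(0, 100, 50, 50)]

    def test_no_detections_all_missed(self):
        m = match_detections([], self.gts)
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_duplicate_detections_one_tp_one_fp(self):
        dets = [_det(0, 0, 50, 50, 0.9), _det(2, 2, 50, 50, 0.8)]
        m = match_detections(dets, [self.gts[0]])
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.assignments == [0, None]  # higher confidence claims the fruit

    def test_perfect_matching(self):
        dets = [_det(b.x, b.y, b.w, b.h, 0.9) for b in self.gts]
        m = match_detections(dets, self.gts)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)

    def test_low_iou_not_matched(self):
        m = match_detections([_det(30, 30, 50, 50, 0.9)], [self.gts[0]])
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_center_criterion(self):
        m = match_detections(
            [_det(30, 30, 50, 50, 0.9)], [self.gts[0]], criterion="center"
        )
        assert m.tp == 0  # center (55,55) outside the box
        m = match_detections(
            [_det(10, 10, 50, 50, 0.9)], [self.gts[0]], criterion="center"
        )
        assert m.tp == 1

    def test_order_invariance(self, rng):
        dets = [
            _det(int(x), int(y), 50, 50, float(c))
            for (x, y), c in zip(rng.integers(0, 150, (8, 2)),
                                 np.linspace(0.71, 0.99, 8))
        ]
        base = match_detections(dets, self.gts)
        for _ in range(5):
            perm = rng.permutation(len(dets))
            m = match_detections([dets[i] for i in perm], self.gts)
            assert (m.tp, m.fp, m.fn) == (base.tp, base.fp, base.fn)


def _mr(tp, fp, fn):
    return MatchResult(tp=tp, fp=fp, fn=fn, assignments=[])


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "tp, fp, fn, recall, precision",
        [
            (135, 8, 15, 90.00, 94.41),   # overall detection result
            (123, 2, 4, 96.85, 98.40),    # validation patches
            (72, 4, 7, 91.14, None),      # overlapped condition
            (42, 3, 8, 84.00, None),      # occluded condition
            (21, 1, 0, 100.00, None),     # separated condition
            (68, 4, 7, 90.67, None),      # sunny
            (67, 4, 8, 89.33, None),      # shaded
        ],
    )
    def test_printed_contingency_counts_reproduce_rates(self, tp, fp, fn, recall, precision):
        rep = compute_metrics(_mr(tp, fp, fn))
        assert rep.recall_pct == recall
        if precision is not None:
            assert rep.precision_pct == precision

    def test_headline_f1(self):
        rep = compute_metrics(_mr(135, 8, 15))
        assert rep.f1_pct == 92.15
        assert rep.false_rate_pct == 5.59
        assert rep.missed_rate_pct == 10.00

    def test_false_rates_by_light(self):
        assert compute_metrics(_mr(68, 4, 7)).false_rate_pct == 5.56
        assert compute_metrics(_mr(67, 4, 8)).false_rate_pct == 5.63

    def test_degenerate_zero_detections(self):
        rep = compute_metrics(_mr(0, 0, 5))
        assert (rep.recall_pct, rep.precision_pct, rep.f1_pct) == (0.0, 0.0, 0.0)

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(_mr(0, 3, 0))

    @settings(deadline=None, max_examples=60)
    @given(tp=st.integers(0, 200), fp=st.integers(0, 200), fn=st.integers(0, 200))
    def test_f1_between_recall_and_precision(self, tp, fp, fn):
        if tp + fn == 0:
            return
        rep = compute_metrics(_mr(tp, fp, fn))
        lo = min(rep.recall_pct, rep.precision_pct)
        hi = max(rep.recall_pct, rep.precision_pct)
        assert lo - 0.01 <= rep.f1_pct <= hi + 0.01


class TestF1FromRates:
    @pytest.mark.parametrize(
        "recall, precision, f1",
        [
            (91.33, 86.16, 88.67),  # ablated pipeline (no color filter)
            (88.00, 92.31, 90.10),  # single-shot CNN baseline
            (77.33, 94.31, 84.98),  # boosted Haar-cascade baseline
            (90.00, 94.41, 92.15),  # full pipeline
        ],
    )
    def test_printed_pairs(self, recall, precision, f1):
        assert f1_from_rates(recall, precision) == f1

    def test_zero_rates(self):
        assert f1_from_rates(0.0, 0.0) == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1]) == 1.0

    def test_chance_level_on_random_labels(self, rng):
        scores = rng.uniform(0, 1, 4000)
        labels = rng.choice([-1, 1], 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_interleaved_example(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, -1, 1, -1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_concordance_with_ties(self, rng):
        scores = np.round(rng.uniform(0, 1, 50), 1)  # duplicates force ties
        labels = rng.choice([-1, 1], 50)
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            auc_concordance(scores, labels), abs=1e-12
        )


class TestEvaluateConditions:
    def test_stratified_counts(self):
        gts = [BoundingBox(0, 0, 50, 50), BoundingBox(100, 100, 50, 50)]
        per_scene = [
            {
                "detections": [_det(0, 0, 50, 50, 0.9)],
                "boxes": gts,
                "condition": ["separated", "occluded"],
                "illumination": "sunny",
            }
        ]
        rep = evaluate_conditions(per_scene)
        sep = rep[rep.condition == "separated"].iloc[0]
        occ = rep[rep.condition == "occluded"].iloc[0]
        allr = rep[rep.condition == "all"].iloc[0]
        assert sep.correct == 1 and sep.correct_rate == 100.0
        assert occ.missed == 1 and occ.missed_rate == 100.0
        assert allr.correct == 1 and allr["count"] == 2

    def test_perfect_detections_are_perfect(self):
        gts = [BoundingBox(10, 10, 40, 40)]
        per_scene = [
            {
                "detections": [_det(10, 10, 40, 40, 0.95)],
                "boxes": gts,
                "condition": ["separated"],
                "illumination": "shaded",
            }
        ]
        rep = evaluate_conditions(per_scene)
        allr = rep[rep.condition == "all"].iloc[0]
        assert allr.correct_rate == 100.0 and allr.false == 0 and allr.missed == 0
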