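"""Detection metrics from raw contingency counts.

Replays TP/FP/FN counts through the evaluation arithmetic: recall and
missed rate over the ground-truth total, precision and false rate over the
detections, F1 as the harmonic mean — all as percentages rounded half-up
to two decimals, the convention of detection result tables.
"""

from tomatodet.evaluation import MatchResult, compute_metrics, f1_from_rates

rows = [
    ("all conditions", 135, 8, 15),
    ("validation patches", 123, 2, 4),
    ("separated", 21, 1, 0),
    ("overlapped", 72, 4, 7),
    ("occluded", 42, 3, 8),
]
print(f"{'set':<20}{'recall%':>9}{'prec%':>9}{'F1%':>9}{'false%':>9}{'miss%':>9}")
for name, tp, fp, fn in rows:
    m = compute_metrics(MatchResult(tp=tp, fp=fp, fn=fn, assignments=[]))
    print(f"{name:<20}{m.recall_pct:>9.2f}{m.precision_pct:>9.2f}{m.f1_pct:>9.2f}"
          f"{m.false_rate_pct:>9.2f}{m.missed_rate_pct:>9.2f}")

print("\nF1 recomputed from already-rounded rate pairs:")
for r, p in [(91.33, 86.16), (88.00, 92.31), (77.33, 94.31)]:
    print(f"  recall {r}%, precision {p}%  ->  F1 {f1_from_rates(r, p)}%")
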