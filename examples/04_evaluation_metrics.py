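"""The evaluation-metric suite on small worked instances.

Every statistic the pipeline reports, on inputs small enough to check by
hand: box IoU, interpolated average precision, Dice, counting accuracy and
precision, identity-line regression, and the paired t-test used to compare
magnifications.
"""

from stomx import (
    StomaBox,
    average_precision,
    counting_accuracy,
    counting_precision,
    dice,
    identity_regression,
    paired_ttest,
)
import numpy as np

truths = [StomaBox(0, 0, 10, 10), StomaBox(30, 0, 40, 10)]
dets = [
    StomaBox(1, 0, 11, 10, score=0.98),   # good match
    StomaBox(60, 60, 70, 70, score=0.95), # false positive
    StomaBox(30, 1, 40, 11, score=0.90),  # good match
]
res = average_precision(dets, truths, iou_thr=0.6)
print(f"AP {res.ap:.4f}  (TP {res.n_tp}, FP {res.n_fp}, FN {res.n_fn})")

a = np.zeros((4, 4), int); a[:2] = 1
b = np.zeros((4, 4), int); b[1:3] = 1
print(f"Dice of half-overlapping masks: {dice(a, b):.3f}")

print(f"counting accuracy (auto 98, manual 100): {counting_accuracy(98, 100):.3f}")
print(f"counting precision (manual 50, auto 100): {counting_precision(50, 100):+.4f}")
print("  (negative = overcounting, positive = undercounting)")

manual = [27, 31, 24, 35, 29]
automatic = [26, 31, 25, 36, 29]
fit = identity_regression(manual, automatic)
print(f"identity regression: R^2 {fit.r2:.4f}, RMSE {fit.rmse:.4f}")

x10 = [16.8, 17.2, 15.9, 16.4]
x20 = [13.5, 14.1, 13.0, 13.8]
t = paired_ttest(x10, x20)
print(f"paired t-test x10 vs x20 index: t {t['t']:.3f}, df {t['df']}, p {t['p']:.2e}")
# A significant t confirms the index shifts with magnification, which is why
# comparisons must hold the field of view fixed.
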