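"""Evaluation statistics for detection, segmentation, counting and the index.

Covers box IoU, interpolated average precision with greedy score-ordered
matching, the Dice coefficient, counting/index accuracy (relative absolute
error complement) and precision (log10 of the manual/automatic ratio, sign
encoding under- vs overcounting), agreement with the identity line y = x
(R^2 and RMSE), summary tables (min/max/mean/SD, CV, Pearson r, paired
t-test), and average-running-time bookkeeping.

Undefined quantities (zero counts, zero truths) are returned as ``None``
rather than silently coerced to a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import StomaBox

__all__ = [
    "iou",
    "DetectionEvalResult",
    "average_precision",
    "dice",
    "counting_accuracy",
    "counting_precision",
    "index_accuracy",
    "index_precision",
    "RegressionFit",
    "identity_regression",
    "summarize",
    "coefficient_of_variation",
    "paired_ttest",
    "pearson",
    "TimingReport",
    "measure_art",
]


def iou(a: StomaBox, b: StomaBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


@dataclass
class DetectionEvalResult:
    ap: Optional[float]
    n_tp: int
    n_fp: int
    n_fn: int
    iou_threshold: float
    pr_points: List[Tuple[float, float]] = field(default_factory=list)  # (recall, precision)


def _greedy_match(
    detections: Sequence[StomaBox], truths: Sequence[StomaBox], iou_thr: float
) -> List[bool]:
    """Greedy one-to-one matching by descending score.

    Each detection (ties broken by box coordinates for determinism) claims
    the unmatched truth with the highest IoU strictly above ``iou_thr``.
    Returns a TP flag per detection, in the sorted order used by the caller.
    """
    order = sorted(
        range(len(detections)),
        key=lambda i: (-(detections[i].score or 0.0), detections[i]),
    )
    matched = [False] * len(truths)
    flags = []
    for i in order:
        best, best_iou = -1, iou_thr
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(detections[i], t)
            if v > best_iou:
                best, best_iou = j, v
        if best >= 0:
            matched[best] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def average_precision(
    detections: Sequence[StomaBox],
    truths: Sequence[StomaBox],
    iou_thr: float = 0.6,
) -> DetectionEvalResult:
    """AP as the area under the all-point interpolated precision-recall curve.

    A detection is a true positive when it claims a ground-truth box with
    IoU strictly above ``iou_thr`` (greedy, score-ordered, one-to-one).
    With zero ground-truth boxes the AP is undefined (``None``).
    """
    if len(truths) == 0:
        return DetectionEvalResult(None, 0, len(detections), 0, iou_thr)
    flags = _greedy_match(detections, truths, iou_thr)
    tp = np.cumsum(flags) if flags else np.array([])
    fp = np.cumsum([not f for f in flags]) if flags else np.array([])
    n_t = len(truths)
    recall = tp / n_t if len(tp) else np.array([])
    precision = tp / (tp + fp) if len(tp) else np.array([])
    pr = list(zip(recall.tolist(), precision.tolist()))
    # all-point interpolation: precision at recall r is max precision at >= r
    ap = 0.0
    prev_r = 0.0
    for k in range(len(recall)):
        r = recall[k]
        if r > prev_r:
            p_interp = precision[k:].max()
            ap += (r - prev_r) * p_interp
            prev_r = r
    n_tp = int(tp[-1]) if len(tp) else 0
    n_fp = int(fp[-1]) if len(fp) else 0
    return DetectionEvalResult(float(ap), n_tp, n_fp, n_t - n_tp, iou_thr, pr)


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN) over pixels of binary masks.

    Two empty masks overlap perfectly (Dice 1).
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    tp = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * tp / denom)


def counting_accuracy(automatic: float, manual: float) -> Optional[float]:
    """1 - |automatic - manual| / manual; undefined (None) when manual is 0.

    May be negative for gross overcounts.
    """
    if manual == 0:
        return None
    return 1.0 - abs(automatic - manual) / manual


def counting_precision(
    manual: float, automatic: float, base: float = 10.0
) -> Optional[float]:
    """log(manual / automatic): negative = overcounting, positive = undercounting.

    Undefined (None) when either count is zero.  Base 10 by default; pass
    ``base=math.e`` for natural log.
    """
    if manual == 0 or automatic == 0:
        return None
    return math.log(manual / automatic, base)


def index_accuracy(automatic_idx: float, manual_idx: float) -> Optional[float]:
    """Stomatal-index accuracy: same functional form as counting accuracy."""
    return counting_accuracy(automatic_idx, manual_idx)


def index_precision(
    manual_idx: float, automatic_idx: float, base: float = 10.0
) -> Optional[float]:
    """Stomatal-index precision: same functional form as counting precision."""
    return counting_precision(manual_idx, automatic_idx, base)


@dataclass
class RegressionFit:
    """Agreement of automatic (y) with manual (x) values against the y = x line."""

    r2: float
    rmse: float
    x: np.ndarray
    y: np.ndarray
    y_bar: float


def identity_regression(manual: Sequence[float], automatic: Sequence[float]) -> RegressionFit:
    """R^2 and RMSE of automatic values against the identity line y = x.

    R^2 = 1 - sum (x_i - y_i)^2 / sum (x_i - x_bar)^2, with the total sum of
    squares taken about the mean of the manual values; RMSE is the root mean
    squared manual-automatic difference.
    """
    x = np.asarray(manual, float)
    y = np.asarray(automatic, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two paired samples of equal length")
    ss_res = float(((x - y) ** 2).sum())
    xbar = float(x.mean())
    ss_tot = float(((x - xbar) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("manual values are constant; R^2 undefined")
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / x.size)
    return RegressionFit(r2, rmse, x, y, xbar)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV = SD / mean (sample SD, ddof=1 when n > 1)."""
    v = np.asarray(values, float)
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(sd / mean)


def summarize(records: Dict[str, Sequence[Optional[float]]]) -> Dict[str, dict]:
    """Min/max/mean/SD table per trait, skipping undefined (None) entries.

    ``records`` maps trait name -> sequence of per-image values; the returned
    dict maps trait -> {min, max, mean, sd, n, n_undefined}.
    """
    out: Dict[str, dict] = {}
    for name, vals in records.items():
        defined = np.asarray([v for v in vals if v is not None], float)
        n_undef = sum(1 for v in vals if v is None)
        if defined.size == 0:
            out[name] = {"min": None, "max": None, "mean": None, "sd": None,
                         "n": 0, "n_undefined": n_undef}
            continue
        out[name] = {
            "min": float(defined.min()),
            "max": float(defined.max()),
            "mean": float(defined.mean()),
            "sd": float(defined.std(ddof=1)) if defined.size > 1 else 0.0,
            "n": int(defined.size),
            "n_undefined": n_undef,
        }
    return out


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sided paired t-test (e.g. x10 vs x20 stomatal indices).

    Returns {t, df, p}; flags zero-variance differences as undefined.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return {"t": None, "df": a.size - 1, "p": None, "undefined": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "df": a.size - 1, "p": float(p), "undefined": False}


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation coefficient."""
    r, _ = stats.pearsonr(np.asarray(a, float), np.asarray(b, float))
    return float(r)


@dataclass
class TimingReport:
    """Average running time per image across the pipeline stages."""

    t_stoma: float
    t_cell: float
    t_si: float
    n_images: int
    art: float


def measure_art(t_stoma: float, t_cell: float, t_si: float, n_images: int) -> TimingReport:
    """ART = (T_stoma + T_cell + T_SI) / N, in seconds per image."""
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    art = (t_stoma + t_cell + t_si) / n_images
    return TimingReport(t_stoma, t_cell, t_si, n_images, art)
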