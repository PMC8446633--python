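"""Evaluation statistics: IoU, AP, Dice, counting metrics, regression, ART."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stomx import (
    StomaBox,
    average_precision,
    coefficient_of_variation,
    counting_accuracy,
    counting_precision,
    dice,
    identity_regression,
    index_accuracy,
    index_precision,
    iou,
    measure_art,
    paired_ttest,
    pearson,
    summarize,
)
def test_iou_examples():
    a = StomaBox(0, 0, 10, 10)
    assert iou(a, a) == 1.0
    assert iou(a, StomaBox(20, 20, 30, 30)) == 0.0
    assert iou(a, StomaBox(5, 0, 15, 10)) == pytest.approx(50 / 150, abs=1e-12)
    assert iou(a, StomaBox(5, 0, 15, 10)) == iou(StomaBox(5, 0, 15, 10), a)


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def _oracle_match(subset, truths, iou_thr):
    """Re-derived greedy matcher: each detection, in score order with ties
    broken by coordinates, claims the unmatched truth of highest IoU
    strictly above the threshold."""
    taken = set()
    tp = 0
    for d in subset:
        best_j, best_v = None, iou_thr
        for j, t in enumerate(truths):
            if j in taken:
                continue
            v = iou(d, t)
            if v > best_v:
                best_j, best_v = j, v
        if best_j is not None:
            taken.add(best_j)
            tp += 1
    return tp


def _ap_oracle(detections, truths, iou_thr):
    """Exhaustive rank sweep: for every cut k rebuild the PR point from
    scratch on the top-k detections, then integrate the interpolated
    envelope.  Independent of the cumulative-sum implementation.
    """
    order = sorted(detections, key=lambda b: (-b.score, b.xmin, b.ymin, b.xmax, b.ymax))
    points = []
    for k in range(1, len(order) + 1):
        tp = _oracle_match(order[:k], truths, iou_thr)
        points.append((tp / len(truths), tp / k))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        if r > prev_r:
            ap += (r - prev_r) * max(p for (r2, p) in points[i:] if r2 >= r)
            prev_r = r
    return ap


def test_ap_perfect_detection_is_one():
    truths = [StomaBox(0, 0, 10, 10), StomaBox(20, 0, 30, 10)]
    dets = [b.with_score(0.99) for b in truths]
    res = average_precision(dets, truths)
    assert res.ap == 1.0 and res.n_tp == 2 and res.n_fp == 0 and res.n_fn == 0


def test_ap_high_scoring_false_positive_halves_ap():
    truth = [StomaBox(0, 0, 10, 10)]
    dets = [StomaBox(50, 50, 60, 60, 0.9), StomaBox(0, 0, 10, 10, 0.8)]
    res = average_precision(dets, truth)
    assert res.ap == pytest.approx(0.5, abs=1e-12)
    assert res.pr_points == [(0.0, 0.0), (1.0, 0.5)]


def test_ap_zero_truths_is_undefined():
    res = average_precision([StomaBox(0, 0, 5, 5, 0.7)], [])
    assert res.ap is None and res.n_fp == 1


def test_ap_equals_exhaustive_threshold_sweep_oracle_on_random_scenes():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n_truth = int(rng.integers(1, 8))
        truths = []
        for _ in range(n_truth):
            x, y = rng.uniform(0, 200, 2)
            truths.append(StomaBox(x, y, x + rng.uniform(5, 30), y + rng.uniform(5, 30)))
        dets = []
        for t in truths:
            if rng.random() < 0.8:  # jittered true detection
                dx, dy = rng.uniform(-4, 4, 2)
                score = round(float(rng.uniform(0.3, 1.0)), 1)  # ties likely
                dets.append(StomaBox(t.xmin + dx, t.ymin + dy, t.xmax + dx, t.ymax + dy, score))
        for _ in range(int(rng.integers(0, 5))):  # false positives
            x, y = rng.uniform(0, 220, 2)
            dets.append(StomaBox(x, y, x + 10, y + 10, round(float(rng.uniform(0, 1)), 1)))
        if not dets:
            continue
        res = average_precision(dets, truths, iou_thr=0.6)
        assert res.ap == pytest.approx(_ap_oracle(dets, truths, 0.6), abs=1e-9)


# ---------------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------------

def test_dice_examples():
    a = np.zeros((4, 4), np.uint8)
    a[:2] = 1
    assert dice(a, a) == 1.0
    b = np.zeros((4, 4), np.uint8)
    b[2:] = 1
    assert dice(a, b) == 0.0
    half = np.zeros((4, 4), np.uint8)
    half[1:3] = 1  # overlaps rows 1 with a (8 px each, 4 shared)
    assert dice(a, half) == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(ValueError):
        dice(a, np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# counting accuracy / precision
# ---------------------------------------------------------------------------

def test_counting_accuracy_examples():
    assert counting_accuracy(100, 100) == 1.0
    assert counting_accuracy(98, 100) == pytest.approx(0.98, abs=1e-12)
    assert counting_accuracy(150, 100) == pytest.approx(0.5, abs=1e-12)
    assert counting_accuracy(5, 0) is None


def test_counting_precision_examples_log10():
    assert counting_precision(100, 100) == 0.0
    assert counting_precision(50, 100) == pytest.approx(math.log10(0.5), abs=1e-12)
    assert counting_precision(100, 50) == pytest.approx(math.log10(2.0), abs=1e-12)
    assert counting_precision(0, 10) is None
    assert counting_precision(10, 0) is None
    # natural-log switch
    assert counting_precision(100, 50, base=math.e) == pytest.approx(math.log(2), abs=1e-12)


@given(st.integers(1, 500), st.integers(1, 500))
def test_counting_precision_antisymmetry(m, a):
    assert counting_precision(m, a) == pytest.approx(-counting_precision(a, m), abs=1e-12)


def test_index_metrics_share_the_functional_forms():
    assert index_accuracy(16.0, 20.0) == pytest.approx(0.8, abs=1e-12)
    assert index_precision(10.0, 20.0) == pytest.approx(math.log10(0.5), abs=1e-12)
    assert index_accuracy(15.0, 15.0) == 1.0
    assert index_precision(15.0, 15.0) == 0.0


# ---------------------------------------------------------------------------
# identity regression
# ---------------------------------------------------------------------------

def test_identity_regression_examples():
    fit = identity_regression([1, 2, 3], [1, 2, 3])
    assert fit.r2 == 1.0 and fit.rmse == 0.0

    fit = identity_regression([1, 2, 3], [1, 2, 4])
    assert fit.rmse == pytest.approx(math.sqrt(1 / 3), abs=1e-12)
    assert fit.r2 == pytest.approx(0.5, abs=1e-12)

    c = 2.5
    fit = identity_regression([1, 2, 3, 4], [1 + c, 2 + c, 3 + c, 4 + c])
    assert fit.rmse == pytest.approx(c, abs=1e-12)

    with pytest.raises(ValueError):
        identity_regression([2, 2, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# summaries, CV, t-test, ART
# ---------------------------------------------------------------------------

def test_summarize_skips_undefined_and_reports_moments():
    rep = summarize({"acc": [1.0, 0.9, None, 0.8]})["acc"]
    assert rep["n"] == 3 and rep["n_undefined"] == 1
    assert rep["min"] == 0.8 and rep["max"] == 1.0
    assert rep["mean"] == pytest.approx(0.9, abs=1e-12)
    assert rep["sd"] == pytest.approx(np.std([1.0, 0.9, 0.8], ddof=1), abs=1e-12)


def test_cv_and_pearson():
    assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0
    vals = [1.0, 2.0, 3.0, 4.0]
    assert coefficient_of_variation(vals) == pytest.approx(
        np.std(vals, ddof=1) / np.mean(vals), abs=1e-12
    )
    assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0, abs=1e-9)


def test_paired_ttest_matches_textbook_formula():
    a = [10.0, 12.0, 9.0]
    b = [8.0, 11.0, 7.5]
    d = np.array(a) - np.array(b)
    t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    res = paired_ttest(a, b)
    assert res["t"] == pytest.approx(t_expected, abs=1e-9)
    assert res["df"] == 2
    ident = paired_ttest([1.0, 2.0], [1.0, 2.0])
    assert ident["undefined"] and ident["t"] is None


def test_measure_art():
    rep = measure_art(2.0, 1.0, 0.5, 10)
    assert rep.art == pytest.approx(0.35, abs=1e-12)
    with pytest.raises(ValueError):
        measure_art(1, 1, 1, 0)
    assert measure_art(2.0, 1.0, 0.5, 20).art == pytest.approx(rep.art / 2, abs=1e-12)
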