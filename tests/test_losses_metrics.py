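"""Metric formulas against brute-force enumeration; BCE-Dice loss facts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from naunet.losses import bce_dice_loss
from naunet.metrics import (ConfusionCounts, accuracy, binarize,
                            confusion_counts, dice, improvement, iou,
                            metric_record, model_comparison, precision,
                            summarize)
from naunet.nn import autograd as ag


def brute_force_counts(pred, gt):
    """Oracle: explicit per-pixel loop."""
    tp = tn = fp = fn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


# -- confusion counting ----------------------------------------------------

def test_confusion_identity_and_complement_cases():
    ones = np.ones((4, 4), dtype=np.uint8)
    c = confusion_counts(ones, ones)
    assert (c.tp, c.tn, c.fp, c.fn) == (16, 0, 0, 0)
    c = confusion_counts(ones, 1 - ones)
    assert c.tp == 0 and c.tn == 0 and c.fp == 16


def test_confusion_four_pixel_enumeration():
    c = confusion_counts([1, 1, 0, 0], [1, 0, 1, 0])
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
    assert accuracy(c) == 0.5 and precision(c) == 0.5


def test_confusion_rejects_bad_inputs():
    with pytest.raises(ValueError, match="binary"):
        confusion_counts([0, 2], [0, 1])
    with pytest.raises(ValueError, match="shape"):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 2)))
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


# -- metric formulas -------------------------------------------------------

def test_metric_values_on_hand_counts():
    c = ConfusionCounts(tp=3, tn=10, fp=1, fn=2)
    assert dice(c) == pytest.approx(6 / 9)
    assert iou(c) == pytest.approx(0.5)
    c = ConfusionCounts(tp=16, tn=0, fp=0, fn=0)
    assert dice(c) == 1.0 and iou(c) == 1.0
    c = ConfusionCounts(tp=0, tn=11, fp=0, fn=5)
    assert dice(c) == 0.0


def test_empty_mask_conventions():
    both_empty = ConfusionCounts(tp=0, tn=16, fp=0, fn=0)
    assert dice(both_empty) == 1.0 and iou(both_empty) == 1.0
    assert precision(both_empty) is None  # no predicted positives


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(0, 2 ** 32 - 1))
def test_metrics_match_brute_force_on_random_masks(seed):
    rng = np.random.default_rng(seed)
    pred = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
    gt = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
    c = confusion_counts(pred, gt)
    tp, tn, fp, fn = brute_force_counts(pred, gt)
    assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
    assert c.total == 256
    if tp + fp + fn:
        assert dice(c) == pytest.approx(2 * tp / (fp + fn + 2 * tp))
        assert iou(c) == pytest.approx(tp / (fp + fn + tp))
    # algebraic identity DC = 2 IoU / (1 + IoU)
    assert dice(c) == pytest.approx(2 * iou(c) / (1 + iou(c)))
    assert dice(c) >= iou(c)


def test_dice_iou_equal_one_iff_masks_identical(rng):
    pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
    c = confusion_counts(pred, pred)
    assert dice(c) == 1.0 and iou(c) == 1.0
    flipped = pred.copy()
    flipped[0, 0] ^= 1
    c2 = confusion_counts(flipped, pred)
    assert dice(c2) < 1.0 and iou(c2) < 1.0


# -- loss ------------------------------------------------------------------

def test_bce_part_is_ln2_for_uniform_half_prediction(rng):
    g = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
    p = np.full_like(g, 0.5)
    loss = bce_dice_loss(p, g)
    assert loss.bce_part == pytest.approx(np.log(2), rel=1e-5)


def test_loss_near_zero_for_perfect_prediction(rng):
    g = (rng.random((2, 1, 8, 8)) > 0.6).astype(np.float32)
    loss = bce_dice_loss(g.copy(), g)
    assert loss.total == pytest.approx(0.0, abs=1e-3)
    assert loss.total == pytest.approx(loss.bce_part + loss.dice_part, rel=1e-6)


def test_loss_ranges_and_monotone_improvement(rng):
    g = (rng.random((1, 1, 16, 16)) > 0.7).astype(np.float32)
    start = 0.5 * g + 0.25
    losses = []
    for t in np.linspace(0.0, 0.98, 8):
        p = (1 - t) * start + t * g
        lv = bce_dice_loss(p, g)
        assert 0.0 <= lv.dice_part <= 1.0
        assert lv.total >= 0.0
        losses.append(lv.total)
    assert all(a > b for a, b in zip(losses, losses[1:]))
    assert losses[-1] < 0.1


def test_loss_gradient_matches_finite_differences(rng):
    g = (rng.random((2, 1, 4, 4)) > 0.5).astype(np.float32)
    p = rng.uniform(0.2, 0.8, size=g.shape).astype(np.float32)
    pt = ag.Tensor(p.copy(), requires_grad=True)
    bce_dice_loss(pt, g).backward()
    eps = 1e-3
    fd = np.zeros_like(p, dtype=np.float64)
    it = np.nditer(p, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = p[idx]
        p[idx] = orig + eps
        hi = bce_dice_loss(p, g).total
        p[idx] = orig - eps
        lo = bce_dice_loss(p, g).total
        p[idx] = orig
        fd[idx] = (hi - lo) / (2 * eps)
    np.testing.assert_allclose(pt.grad, fd, rtol=2e-2, atol=2e-3)


def test_loss_input_validation(rng):
    g = np.zeros((1, 1, 4, 4), dtype=np.float32)
    with pytest.raises(ValueError, match="shape"):
        bce_dice_loss(np.zeros((1, 1, 4, 5)), g)
    with pytest.raises(ValueError, match="binary"):
        bce_dice_loss(np.full_like(g, 0.5), np.full_like(g, 0.3))


def test_binarize_threshold():
    probs = np.array([0.1, 0.5, 0.50001, 0.9])
    np.testing.assert_array_equal(binarize(probs), [0, 0, 1, 1])


# -- summaries -------------------------------------------------------------

def test_summarize_mean_and_sample_std():
    from naunet.metrics import MetricRecord
    records = [MetricRecord("a", 0.7, 0.6, 0.9, 0.8),
               MetricRecord("b", 0.8, 0.7, 0.92, 0.85)]
    s = summarize(records).set_index("metric")
    assert s.loc["dice", "mean"] == pytest.approx(0.75)
    assert s.loc["dice", "std"] == pytest.approx(0.070711, abs=1e-5)
    single = summarize(records[:1]).set_index("metric")
    assert single.loc["dice", "std"] == 0.0


def test_summarize_excludes_undefined_precision():
    from naunet.metrics import MetricRecord
    records = [MetricRecord("a", 0.5, 0.4, 0.9, None),
               MetricRecord("b", 0.6, 0.5, 0.92, 0.7)]
    s = summarize(records).set_index("metric")
    assert s.loc["precision", "mean"] == pytest.approx(0.7)
    assert s.loc["precision", "n"] == 1
    with pytest.raises(ValueError):
        summarize([])


def test_improvement_percentage_formula():
    assert improvement(0.750, 0.745) == pytest.approx(100 * 0.005 / 0.745)
    assert improvement(0.750, 0.745) == pytest.approx(0.6711, abs=1e-4)
    with pytest.raises(ValueError):
        improvement(1.0, 0.0)


def test_model_comparison_improvement_rows():
    from naunet.metrics import MetricRecord
    recs = {"nau": [MetricRecord("a", 0.75, 0.6, 0.96, 0.85)],
            "base": [MetricRecord("a", 0.73, 0.59, 0.95, 0.80)]}
    table = model_comparison(recs, reference="nau")
    row = table[(table["model"] == "nau over base (%)") & (table["metric"] == "dice")]
    assert row["mean"].iloc[0] == pytest.approx(100 * (0.75 - 0.73) / 0.73)
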