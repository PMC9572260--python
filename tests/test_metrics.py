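"""Per-class pixel metrics: formulas, identities, pooling, undefined cases."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatvision import metrics as mx


def brute_force_counts(pred, truth, class_id):
    """Independent oracle: explicit per-pixel loop."""
    tp = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p == class_id and t == class_id:
            tp += 1
        elif p == class_id:
            fp += 1
        elif t == class_id:
            fn += 1
    return tp, fp, fn


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.array([[0, 1], [2, 1]])
        t = mx.confusion(truth, truth, 1)
        assert (t.tp, t.fp, t.fn) == (2, 0, 0)

    def test_hand_counted_toy_mask(self):
        # truth: 6 grain pixels; prediction hits 5 of them and marks two
        # background pixels as grain
        truth = np.zeros((4, 4), dtype=int)
        truth[0, :3] = 1
        truth[1, :3] = 1
        pred = truth.copy()
        pred[1, 2] = 0      # one missed grain pixel
        pred[3, 0] = 1      # two false grain pixels
        pred[3, 1] = 1
        t = mx.confusion(pred, truth, 1)
        assert (t.tp, t.fp, t.fn) == (5, 2, 1)

    def test_all_background_prediction(self):
        truth = np.full((3, 3), 2)
        pred = np.zeros((3, 3), dtype=int)
        t = mx.confusion(pred, truth, 2)
        assert (t.tp, t.fp, t.fn) == (0, 0, 9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            mx.confusion(np.zeros((2, 2)), np.zeros((3, 3)), 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 3, (12, 12))
        truth = rng.integers(0, 3, (12, 12))
        for cid in (1, 2):
            t = mx.confusion(pred, truth, cid)
            assert (t.tp, t.fp, t.fn) == brute_force_counts(pred, truth, cid)


class TestFormulas:
    def test_toy_table_values(self):
        t = mx.ConfusionTable(1, tp=5, fp=2, fn=1)
        assert mx.precision(t) == pytest.approx(0.7143, abs=5e-5)
        assert mx.recall(t) == pytest.approx(0.8333, abs=5e-5)
        assert mx.f1(mx.precision(t), mx.recall(t)) == pytest.approx(0.7692, abs=5e-5)
        assert mx.iou(t) == pytest.approx(0.6250, abs=5e-5)

    def test_f1_harmonic_mean_fixed_point(self):
        for x in (0.2, 0.5, 0.9):
            assert mx.f1(x, x) == pytest.approx(x)

    def test_published_grain_column_identity(self):
        # P=86.86%, R=80.63% must reproduce F1=83.63%
        f1, _ = mx.metrics_from_pr(0.8686, 0.8063)
        assert f1 == pytest.approx(0.8363, abs=1e-4)

    def test_metrics_from_pr_equals_direct_iou(self):
        t = mx.ConfusionTable(1, tp=5, fp=2, fn=1)
        p, r = mx.precision(t), mx.recall(t)
        _, f_iou = mx.metrics_from_pr(p, r)
        assert f_iou == pytest.approx(mx.iou(t), rel=1e-12)

    def test_perfect_pr_gives_perfect_scores(self):
        f1, f_iou = mx.metrics_from_pr(1.0, 1.0)
        assert f1 == 1.0 and f_iou == 1.0

    def test_zero_denominators_return_undefined_marker(self):
        empty = mx.ConfusionTable(1, 0, 0, 0)
        with pytest.warns(UserWarning):
            assert math.isnan(mx.precision(empty))
        with pytest.warns(UserWarning):
            assert math.isnan(mx.recall(empty))
        with pytest.warns(UserWarning):
            assert math.isnan(mx.iou(empty))
        with pytest.warns(UserWarning):
            assert math.isnan(mx.f1(float("nan"), 0.5))

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500), fn=st.integers(0, 500)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_iou_below_min_pr_below_f1(self, tp, fp, fn):
        t = mx.ConfusionTable(1, tp, fp, fn)
        if tp == 0:
            return
        p, r = mx.precision(t), mx.recall(t)
        f1 = mx.f1(p, r)
        iou = mx.iou(t)
        assert iou <= min(p, r) + 1e-12
        assert min(p, r) <= f1 + 1e-12
        assert f1 <= max(p, r) + 1e-12


class TestMiou:
    def test_published_two_class_means(self):
        assert mx.miou([0.7186, 0.7727]) == pytest.approx(0.7457, abs=5e-5)
        assert mx.miou([0.5756, 0.6646]) == pytest.approx(0.6201, abs=5e-5)

    def test_identical_entries(self):
        assert mx.miou([0.4, 0.4]) == pytest.approx(0.4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mx.miou([])

    def test_undefined_entries_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert mx.miou([0.5, float("nan")]) == pytest.approx(0.5)


class TestEvaluateSet:
    def test_perfect_prediction_all_ones(self, rendered):
        summary = mx.evaluate_set([rendered.mask], [rendered.mask])
        for cm in summary.per_class.values():
            assert cm.precision == 1.0 and cm.recall == 1.0
            assert cm.f1 == 1.0 and cm.iou == 1.0
        assert summary.f_miou == 1.0

    def test_duplicating_images_leaves_metrics_unchanged(self, rendered):
        rng = np.random.default_rng(0)
        pred = rendered.mask.copy()
        flip = rng.uniform(size=pred.shape) < 0.1
        pred[flip] = rng.integers(0, 3, int(flip.sum()))
        one = mx.evaluate_set([pred], [rendered.mask])
        two = mx.evaluate_set([pred, pred], [rendered.mask, rendered.mask])
        assert one == two

    def test_pooling_equals_summed_confusions(self, rendered):
        rng = np.random.default_rng(1)
        preds, truths = [], []
        for seed in range(3):
            truth = rng.integers(0, 3, (16, 16))
            pred = rng.integers(0, 3, (16, 16))
            preds.append(pred)
            truths.append(truth)
        summary = mx.evaluate_set(preds, truths)
        for cid in (1, 2):
            pooled = mx.ConfusionTable(cid, 0, 0, 0)
            for p, t in zip(preds, truths):
                pooled = pooled + mx.confusion(p, t, cid)
            assert summary.per_class[cid] == mx.class_metrics(pooled)

    def test_length_mismatch_rejected(self, rendered):
        with pytest.raises(ValueError):
            mx.evaluate_set([rendered.mask], [])

    def test_report_table_contains_all_columns(self, rendered):
        summary = mx.evaluate_set([rendered.mask], [rendered.mask])
        frame = summary.to_frame()
        assert {"class", "P", "R", "F1", "F_IOU", "F_MIOU"} <= set(frame.columns)
        text = summary.format_table()
        assert "grain" in text and "impurity" in text
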