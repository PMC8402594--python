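"""Evaluation metrics against brute-force recomputation and identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polypseg.metrics import (
    ConfusionCounts,
    METRIC_NAMES,
    aggregate_counts,
    aggregate_per_image,
    bin_accuracies,
    compute_metrics,
    confusion_from_masks,
)


def brute_force_confusion(pred, truth):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], truth[i, j]
            if p == 1 and t == 1:
                tp += 1
            elif p == 1 and t == 0:
                fp += 1
            elif p == 0 and t == 0:
                tn += 1
            else:
                fn += 1
    return tp, fp, tn, fn


counts_strategy = st.tuples(
    st.integers(0, 50), st.integers(0, 50),
    st.integers(0, 50), st.integers(0, 50),
).filter(lambda t: sum(t) > 0)


class TestConfusion:
    def test_all_polyp_agreement(self):
        m = np.ones((4, 5), dtype=int)
        c = confusion_from_masks(m, m)
        assert (c.tp, c.fp, c.tn, c.fn) == (20, 0, 0, 0)

    def test_complement_prediction(self):
        truth = np.zeros((4, 4), dtype=int)
        truth[:2] = 1
        c = confusion_from_masks(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0
        assert c.fp == 8 and c.fn == 8

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            pred = (rng.uniform(size=(16, 16)) < 0.4).astype(int)
            truth = (rng.uniform(size=(16, 16)) < 0.3).astype(int)
            c = confusion_from_masks(pred, truth)
            assert (c.tp, c.fp, c.tn, c.fn) == \
                brute_force_confusion(pred, truth)
            assert c.total == 256

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_from_masks(np.array([[2]]), np.array([[1]]))

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_from_masks(np.zeros((2, 2), int), np.zeros((3, 3), int))


class TestComputeMetrics:
    def test_worked_example(self):
        r = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert r.accuracy == pytest.approx(0.8)
        assert r.dice == pytest.approx(0.75)
        assert r.sensitivity == pytest.approx(0.75)
        assert r.precision == pytest.approx(0.75)
        assert r.f2 == pytest.approx(0.75)
        assert r.specificity == pytest.approx(5 / 6)
        assert r.iou_polyp == pytest.approx(3 / 5)

    def test_perfect_prediction_all_ones(self):
        r = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=30, fn=0))
        for name in METRIC_NAMES:
            assert getattr(r, name) == pytest.approx(1.0)

    @given(counts_strategy)
    @settings(max_examples=300, derandomize=True)
    def test_all_metrics_in_unit_interval(self, tpl):
        r = compute_metrics(ConfusionCounts(*tpl))
        for name in METRIC_NAMES:
            assert 0.0 <= getattr(r, name) <= 1.0

    @given(counts_strategy)
    @settings(max_examples=300, derandomize=True)
    def test_dice_iou_identity(self, tpl):
        r = compute_metrics(ConfusionCounts(*tpl))
        assert r.dice == pytest.approx(
            2 * r.iou_polyp / (1 + r.iou_polyp), abs=1e-12)

    @given(counts_strategy)
    @settings(max_examples=300, derandomize=True)
    def test_label_swap_symmetry(self, tpl):
        tp, fp, tn, fn = tpl
        r = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        s = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert r.sensitivity == pytest.approx(s.specificity)
        assert r.iou_polyp == pytest.approx(s.iou_background)
        assert r.accuracy == pytest.approx(s.accuracy)

    def test_mean_iou_is_class_average(self):
        r = compute_metrics(ConfusionCounts(3, 1, 5, 1))
        assert r.mean_iou == pytest.approx((r.iou_polyp + r.iou_background) / 2)

    def test_zero_denominator_conventions(self):
        # no polyp anywhere, none predicted: vacuously perfect
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=9, fn=0))
        assert r.sensitivity == 1.0 and r.precision == 1.0
        assert r.iou_polyp == 1.0 and r.dice == 1.0 and r.f2 == 1.0
        assert "sensitivity" in r.degenerate_flags
        # no polyp in truth but false alarms raised
        r2 = compute_metrics(ConfusionCounts(tp=0, fp=3, tn=6, fn=0))
        assert r2.sensitivity == 0.0
        assert r2.precision == 0.0

    def test_agrees_with_mask_level_recomputation(self, rng):
        for _ in range(50):
            pred = (rng.uniform(size=(8, 8)) < 0.5).astype(int)
            truth = (rng.uniform(size=(8, 8)) < 0.5).astype(int)
            c = confusion_from_masks(pred, truth)
            r = compute_metrics(c)
            tp, fp, tn, fn = brute_force_confusion(pred, truth)
            if tp + fn:
                assert r.sensitivity == pytest.approx(tp / (tp + fn))
            if tp + fp + fn:
                assert r.dice == pytest.approx(2 * tp / (2 * tp + fp + fn))
            assert r.accuracy == pytest.approx((tp + tn) / 64)


class TestAggregation:
    def test_single_report_is_itself(self):
        r = compute_metrics(ConfusionCounts(3, 1, 5, 1))
        agg = aggregate_per_image([r])
        for name in METRIC_NAMES:
            assert getattr(agg, name) == pytest.approx(getattr(r, name))

    def test_mean_of_two(self):
        r1 = compute_metrics(ConfusionCounts(tp=9, fp=0, tn=1, fn=0))
        r2 = compute_metrics(ConfusionCounts(tp=8, fp=1, tn=1, fn=0))
        agg = aggregate_per_image([r1, r2])
        assert agg.accuracy == pytest.approx((r1.accuracy + r2.accuracy) / 2)
        assert agg.aggregation_mode == "per_image_mean"

    def test_permutation_invariance(self, rng):
        reports = [compute_metrics(ConfusionCounts(*rng.integers(0, 20, 4)))
                   for _ in range(6)]
        a = aggregate_per_image(reports)
        b = aggregate_per_image(list(reversed(reports)))
        for name in METRIC_NAMES:
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_dataset_aggregate_pools_counts(self):
        counts = [ConfusionCounts(3, 1, 5, 1), ConfusionCounts(1, 0, 9, 0)]
        agg = aggregate_counts(counts)
        pooled = ConfusionCounts(4, 1, 14, 1)
        direct = compute_metrics(pooled)
        assert agg.mean_iou == pytest.approx(direct.mean_iou)
        assert agg.aggregation_mode == "dataset_aggregate"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_per_image([])


class TestAccuracyBinning:
    def test_worked_example(self):
        assert bin_accuracies([0.95, 0.85, 0.30]) == (1, 1, 0, 0, 0, 1)

    def test_empty_list_all_zeros(self):
        assert bin_accuracies([]) == (0, 0, 0, 0, 0, 0)

    def test_boundaries(self):
        assert bin_accuracies([0.9]) == (1, 0, 0, 0, 0, 0)
        assert bin_accuracies([0.8999]) == (0, 1, 0, 0, 0, 0)
        assert bin_accuracies([0.4999]) == (0, 0, 0, 0, 0, 1)
        assert bin_accuracies([0.0]) == (0, 0, 0, 0, 0, 1)

    def test_counts_sum_to_n(self, rng):
        accs = rng.uniform(0, 1, size=356)
        assert sum(bin_accuracies(accs)) == 356

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_accuracies([1.2])
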