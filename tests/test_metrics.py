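"""Metric definitions, cross-metric identities, trial statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tumorseg.metrics import (
    dice_coefficient,
    evaluate_pairs,
    iou,
    pixel_accuracy,
    summarize_trial_reports,
    summarize_trials,
)
from tumorseg.training import dice_loss

binary_mask = arrays(np.uint8, (12, 12), elements=st.integers(0, 1))


class TestPixelAccuracy:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        assert pixel_accuracy(m, m) == 1.0

    def test_complement_masks(self, rng):
        m = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        assert pixel_accuracy(1 - m, m) == 0.0

    def test_hand_counted_example(self):
        assert pixel_accuracy([[1, 0], [0, 0]], [[1, 1], [0, 0]]) == pytest.approx(3 / 4)


class TestDiceAndIoU:
    def test_identical_nonempty(self, rng):
        m = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        m[0, 0] = 1
        assert dice_coefficient(m, m) == 1.0
        assert iou(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_coefficient(a, b) == 0.0
        assert iou(a, b) == 0.0

    def test_set_count_example(self):
        # |P|=3, |O|=3, overlap 2 -> DSC = 4/6, IoU = 2/4
        p = np.array([1, 1, 1, 0, 0], dtype=np.uint8)
        o = np.array([1, 1, 0, 1, 0], dtype=np.uint8)
        assert dice_coefficient(p, o) == pytest.approx(2 * 2 / 6)
        assert iou(p, o) == pytest.approx(2 / 4)

    def test_both_empty_score_one(self):
        z = np.zeros((5, 5), dtype=np.uint8)
        assert dice_coefficient(z, z) == 1.0 and iou(z, z) == 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            dice_coefficient(np.array([0, 2]), np.array([0, 1]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            iou(np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(p=binary_mask, o=binary_mask)
    def test_dice_iou_identity(self, p, o):
        d, j = dice_coefficient(p, o), iou(p, o)
        assert abs(d - 2 * j / (1 + j)) <= 1e-12
        assert 0.0 <= d <= 1.0 and 0.0 <= j <= 1.0 and j <= d

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(p=binary_mask, o=binary_mask, seed=st.integers(0, 2**16))
    def test_permutation_invariance(self, p, o, seed):
        perm = np.random.default_rng(seed).permutation(p.size)
        pp = p.ravel()[perm].reshape(p.shape)
        op = o.ravel()[perm].reshape(o.shape)
        assert dice_coefficient(pp, op) == pytest.approx(dice_coefficient(p, o))
        assert pixel_accuracy(pp, op) == pytest.approx(pixel_accuracy(p, o))

    def test_hard_dice_equals_one_minus_loss_in_small_smooth_limit(self, rng):
        p = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        o = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        assert dice_coefficient(p, o) == pytest.approx(
            1.0 - dice_loss(p.astype(float), o, smooth=1e-12), abs=1e-9)


class TestTrialStatistics:
    def test_constant_trials(self):
        s = summarize_trials([0.5, 0.5, 0.5])
        assert (s.mean, s.sd) == (0.5, 0.0)

    def test_hand_computed_sample_sd(self):
        s = summarize_trials([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)  # (n-1) denominator

    def test_seven_equal_trials_sd_zero(self):
        assert summarize_trials([0.9046] * 7).sd == 0.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            summarize_trials([0.5])

    def test_trial_report_summary(self):
        trials = [{"accuracy": a, "dice": d, "iou": i}
                  for a, d, i in [(0.99, 0.9, 0.82), (0.98, 0.92, 0.85), (0.99, 0.91, 0.83)]]
        out = summarize_trial_reports(trials)
        assert out["dice"].mean == pytest.approx(0.91)
        assert out["iou"].sd > 0


class TestEvaluatePairs:
    def test_per_slice_and_pooled_agree_on_perfect_predictions(self, rng):
        pairs = []
        for i in range(4):
            m = (rng.random((8, 8)) < 0.3).astype(np.uint8)
            pairs.append((f"s{i}", m, m))
        for mode in ("per_slice", "pooled"):
            rep = evaluate_pairs(pairs, mode=mode)
            assert rep.aggregate == {"accuracy": 1.0, "dice": 1.0, "iou": 1.0}

    def test_per_sample_table_columns(self, rng):
        m = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        rep = evaluate_pairs([("a", m, m)])
        assert list(rep.per_sample.columns) == ["id", "accuracy", "dice", "iou"]
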