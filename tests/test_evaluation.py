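import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from origamiflex import (
    HINGE,
    BoundingBox,
    match_detections,
    mean_angle_error,
    precision_recall_f1,
    spatial_errors,
)
from tests.conftest import hinge_pose


class TestMatchDetections:
    def test_perfect_predictions(self):
        gt = [BoundingBox(10, 10, 5, 5), BoundingBox(50, 50, 5, 5)]
        pred = [BoundingBox(10, 10, 5, 5, 0.8), BoundingBox(50, 50, 5, 5, 0.6)]
        result = match_detections(pred, gt)
        assert (result.tp, result.fp, result.fn) == (2, 0, 0)

    def test_no_predictions(self):
        gt = [BoundingBox(10, 10, 5, 5)]
        result = match_detections([], gt)
        assert (result.tp, result.fp, result.fn) == (0, 0, 1)

    def test_one_to_one_constraint(self):
        """Two overlapping predictions on one truth: one TP, one FP."""
        gt = [BoundingBox(10, 10, 6, 6)]
        pred = [BoundingBox(10, 10, 6, 6, 0.9), BoundingBox(11, 10, 6, 6, 0.7)]
        result = match_detections(pred, gt, 0.3)
        assert (result.tp, result.fp, result.fn) == (1, 1, 0)

    def test_below_threshold_is_fp_and_fn(self):
        gt = [BoundingBox(10, 10, 5, 5)]
        pred = [BoundingBox(30, 30, 5, 5, 0.9)]
        result = match_detections(pred, gt, 0.3)
        assert (result.tp, result.fp, result.fn) == (0, 1, 1)

    def test_equal_confidence_order_invariance(self):
        gt = [BoundingBox(10, 10, 6, 6), BoundingBox(16, 10, 6, 6)]
        pred = [BoundingBox(10, 10, 6, 6, 0.5), BoundingBox(16, 10, 6, 6, 0.5)]
        a = match_detections(pred, gt, 0.3)
        b = match_detections(pred[::-1], gt, 0.3)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn) == (2, 0, 0)


class TestPrecisionRecallF1:
    def test_undefined_precision_reported_as_none(self):
        metrics = precision_recall_f1(0, 0, 3)
        assert metrics.precision is None
        assert metrics.recall == 0.0
        assert metrics.f1 is None

    def test_degenerate_zero_scores(self):
        metrics = precision_recall_f1(0, 5, 3)
        assert metrics.precision == 0.0
        assert metrics.recall == 0.0
        assert metrics.f1 == 0.0
        assert metrics.degenerate

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(0, 0, 0)
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 1)

    @given(tp=st.integers(0, 2000), fp=st.integers(0, 2000), fn=st.integers(0, 2000))
    def test_f1_is_harmonic_mean_bounded(self, tp, fp, fn):
        if tp + fp + fn == 0 or tp + fp == 0 or tp + fn == 0:
            return
        m = precision_recall_f1(tp, fp, fn)
        lo, hi = sorted((m.precision, m.recall))
        assert 0.0 <= m.f1 <= 1.0
        assert m.f1 <= 2 * lo + 1e-12
        if m.f1 > 0:
            assert lo - 1e-12 <= m.f1 <= hi + 1e-12


class TestMeanAngleError:
    def test_identical_poses_zero_error(self):
        gt = [hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0))]
        assert mean_angle_error(gt, gt) == 0.0

    def test_arithmetic_mean_of_absolute_errors(self):
        gt = [
            hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0)),  # 90 deg
            hinge_pose("b", HINGE, (0, 10), (0, 0), (10, 0)),
        ]
        pred = [
            hinge_pose("a", HINGE, (np.tan(np.radians(2)) * 10, 10), (0, 0), (10, 0)),
            hinge_pose("b", HINGE, (-np.tan(np.radians(6)) * 10, 10), (0, 0), (10, 0)),
        ]
        assert mean_angle_error(pred, gt) == pytest.approx(4.0, abs=1e-9)

    def test_tip_swap_does_not_matter(self):
        gt = [hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0))]
        pred = [hinge_pose("a", HINGE, (1, 9), (0, 0), (9, 1))]
        swapped = [hinge_pose("a", HINGE, (9, 1), (0, 0), (1, 9))]
        assert mean_angle_error(pred, gt) == pytest.approx(
            mean_angle_error(swapped, gt), abs=1e-12
        )

    def test_no_pairs_raises(self):
        gt = [hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0))]
        pred = [hinge_pose("other", HINGE, (0, 10), (0, 0), (10, 0))]
        with pytest.raises(ValueError):
            mean_angle_error(pred, gt)


class TestSpatialErrors:
    def test_identical_poses(self):
        gt = [hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0))]
        metrics = spatial_errors(gt, gt, nm_per_px=1.0)
        assert metrics.flip_rate == 0.0
        assert all(v == 0.0 for v in metrics.per_point_2d_std.values())

    def test_constant_offset_is_pure_bias(self):
        """A constant (3, 4) px shift at 1 nm/px: every error vector is
        (3, 4) nm and the spread is exactly zero."""
        gt = [
            hinge_pose(f"p{i}", HINGE, (0, 30), (0, 0), (30, i)) for i in range(5)
        ]
        pred = [
            hinge_pose(f"p{i}", HINGE, (0, 30), (3, 4), (30, i)) for i in range(5)
        ]
        metrics = spatial_errors(pred, gt, nm_per_px=1.0)
        vecs = metrics.per_point_error_vectors["vertex"]
        assert np.allclose(vecs, [3.0, 4.0])
        assert metrics.per_point_2d_std["vertex"] == 0.0
        assert metrics.per_point_mean_radial_error["vertex"] == pytest.approx(5.0)

    def test_isotropic_noise_gives_sqrt2_sigma(self):
        """i.i.d. Gaussian noise of sigma = 2 nm per coordinate gives a 2D
        standard deviation of 2*sqrt(2) nm."""
        rng = np.random.default_rng(6)
        n = 10_000
        gt, pred = [], []
        noise = rng.normal(0, 2.0, size=(n, 2))
        for i in range(n):
            gt.append(hinge_pose(f"p{i}", HINGE, (0, 30), (0, 0), (30, 0)))
            pred.append(hinge_pose(
                f"p{i}", HINGE, (0, 30),
                (noise[i, 0], noise[i, 1]), (30, 0),
            ))
        metrics = spatial_errors(pred, gt, nm_per_px=1.0, canonicalize=False)
        assert metrics.per_point_2d_std["vertex"] == pytest.approx(
            2 * np.sqrt(2), rel=0.05
        )

    def test_flip_rate_counts_swapped_predictions(self):
        gt = [
            hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0)),
            hinge_pose("b", HINGE, (0, 10), (0, 0), (10, 0)),
        ]
        pred = [
            hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0)),
            hinge_pose("b", HINGE, (10, 0), (0, 0), (0, 10)),  # swapped tips
        ]
        metrics = spatial_errors(pred, gt, nm_per_px=1.0)
        assert metrics.flip_rate == 0.5

    def test_missing_calibration_rejected(self):
        gt = [hinge_pose("a", HINGE, (0, 10), (0, 0), (10, 0))]
        with pytest.raises(ValueError):
            spatial_errors(gt, gt, nm_per_px=0.0)
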