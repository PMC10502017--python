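import numpy as np
import pytest

from origamiflex import (
    HINGE,
    HINGE_NUCLEOSOME,
    STERIDYN,
    BoundingBox,
    KeypointPose,
    Point2D,
    SimulationConfig,
    canonicalize_tip_labels,
    classical_pose,
    crop_particles,
    filter_pose_confidence,
    generate_micrograph,
    map_pose_to_micrograph,
)
from tests.conftest import hinge_pose

ANGLE_POINTS = ("tip_a", "vertex", "tip_b")


def _crop_of(micrograph, record, out_size=200, pad=1.2):
    side = max(record.true_box.w, record.true_box.h) * pad
    box = BoundingBox(record.true_box.cx, record.true_box.cy, side, side)
    (crop,) = crop_particles(micrograph, [box], out_size)
    return crop


class TestClassicalPoseHinge:
    def test_clean_crop_recovers_angle(self, clean_single_hinge):
        _, micrograph, records = clean_single_hinge
        record = records[0]
        crop = _crop_of(micrograph, record)
        pose = classical_pose(crop.image, HINGE)
        assert pose.is_complete(ANGLE_POINTS)
        assert pose.angle() == pytest.approx(record.true_angle, abs=4.0)

    def test_rotated_crop_same_angle(self, clean_single_hinge):
        """The included angle is orientation-free: a 90-degree image
        rotation must not change the estimate."""
        _, micrograph, records = clean_single_hinge
        crop = _crop_of(micrograph, records[0])
        pose = classical_pose(crop.image, HINGE)
        rotated = classical_pose(np.rot90(crop.image).copy(), HINGE)
        assert abs(pose.angle() - rotated.angle()) <= 1.0

    def test_blank_crop_fails_softly(self):
        pose = classical_pose(np.zeros((200, 200)), HINGE)
        assert pose.points == {}
        assert all(pose.confidence(n) == 0.0 for n in ANGLE_POINTS)

    def test_rod_is_not_a_hinge(self):
        """A straight rod has no vertex: the estimator must refuse it
        rather than report a ~180-degree angle with high confidence."""
        img = np.zeros((200, 200))
        img[90:110, 20:180] = 1.0
        pose = classical_pose(img, HINGE)
        assert pose.points == {}

    def test_vertex_more_precise_than_tips(self, small_scene):
        """Tip ends fray (tapered render), so tip localization is noisier
        than the vertex, matching the real annotation experience."""
        _, micrograph, records = small_scene
        v_err, t_err = [], []
        for record in records:
            if record.particle_class != "target_hinge":
                continue
            crop = _crop_of(micrograph, record)
            pose = classical_pose(crop.image, HINGE)
            if not pose.is_complete(ANGLE_POINTS):
                continue
            pose = map_pose_to_micrograph(pose, crop)
            pose, _ = canonicalize_tip_labels(pose, record.true_pose)
            gt = record.true_pose
            v_err.append(pose.get("vertex").distance_to(gt.get("vertex")))
            t_err.append(pose.get("tip_a").distance_to(gt.get("tip_a")))
            t_err.append(pose.get("tip_b").distance_to(gt.get("tip_b")))
        assert len(v_err) >= 10
        assert np.median(v_err) <= np.median(t_err)


class TestClassicalPoseOtherDevices:
    def test_nucleosome_point_found(self):
        config = SimulationConfig(
            seed=21, device="hinge_nucleosome", n_target_hinges=2,
            n_vertical_distractors=0, n_aggregates=0, n_free_blobs=0,
            n_boundary_fragments=0, noise_sd=0.0, mottle_sd=0.0,
        )
        micrograph, records = generate_micrograph(config)
        found = 0
        for record in records:
            crop = _crop_of(micrograph, record)
            pose = classical_pose(crop.image, HINGE_NUCLEOSOME)
            if pose.get("nucleosome") is None:
                continue
            pose = map_pose_to_micrograph(pose, crop)
            err = pose.get("nucleosome").distance_to(
                record.true_pose.get("nucleosome"))
            assert err <= 6.0
            found += 1
        assert found >= 1

    def test_steridyn_two_angles_recovered(self):
        config = SimulationConfig(
            seed=31, device="steridyn", n_target_hinges=3,
            n_vertical_distractors=0, n_aggregates=0, n_free_blobs=0,
            n_boundary_fragments=0, noise_sd=0.0, mottle_sd=0.0,
        )
        micrograph, records = generate_micrograph(config)
        recovered = 0
        for record in records:
            crop = _crop_of(micrograph, record)
            pose = classical_pose(crop.image, STERIDYN)
            if not pose.is_complete():
                continue
            pose = map_pose_to_micrograph(pose, crop)
            pred = sorted(pose.angles())
            true = sorted(record.true_angles)
            if max(abs(p - t) for p, t in zip(pred, true)) <= 8.0:
                recovered += 1
        assert recovered >= 2


class TestPoseFilters:
    def test_confidence_gate_all_points_must_pass(self):
        kept = hinge_pose("a", HINGE, (0, 1), (0, 0), (1, 0), (0.95, 0.93, 0.99))
        dropped = hinge_pose("b", HINGE, (0, 1), (0, 0), (1, 0), (0.95, 0.91, 0.99))
        out = filter_pose_confidence([kept, dropped], 0.92)
        assert [p.particle_id for p in out] == ["a"]

    def test_empty_and_incomplete(self):
        assert filter_pose_confidence([], 0.92) == []
        incomplete = KeypointPose("c", HINGE, {"vertex": (Point2D(0, 0), 0.99)})
        assert filter_pose_confidence([incomplete], 0.92) == []


class TestCanonicalizeTips:
    def test_identity_when_matched(self):
        ref = hinge_pose("r", HINGE, (0, 10), (0, 0), (10, 0))
        pred = hinge_pose("p", HINGE, (1, 10), (0, 0), (10, 1))
        out, flipped = canonicalize_tip_labels(pred, ref)
        assert not flipped
        assert out.get("tip_a") == pred.get("tip_a")

    def test_swap_detected_and_resolved(self):
        ref = hinge_pose("r", HINGE, (0, 10), (0, 0), (10, 0))
        pred = hinge_pose("p", HINGE, (10, 0), (0, 0), (0, 10))
        out, flipped = canonicalize_tip_labels(pred, ref)
        assert flipped
        assert out.get("tip_a").distance_to(ref.get("tip_a")) == 0.0
        assert out.get("tip_b").distance_to(ref.get("tip_b")) == 0.0

    def test_tie_keeps_original_labels(self):
        ref = hinge_pose("r", HINGE, (0, 10), (0, 0), (10, 0))
        pred = hinge_pose("p", HINGE, (5, 5), (0, 0), (5, 5))
        _, flipped = canonicalize_tip_labels(pred, ref)
        assert not flipped

    def test_swap_never_changes_angle(self):
        ref = hinge_pose("r", HINGE, (0, 10), (0, 0), (10, 0))
        pred = hinge_pose("p", HINGE, (10, 1), (1, 1), (0, 9))
        out, _ = canonicalize_tip_labels(pred, ref)
        assert out.angle() == pytest.approx(pred.angle(), abs=1e-9)

    def test_missing_tip_raises(self):
        ref = hinge_pose("r", HINGE, (0, 10), (0, 0), (10, 0))
        incomplete = KeypointPose("p", HINGE, {"vertex": (Point2D(0, 0), 1.0)})
        with pytest.raises(ValueError):
            canonicalize_tip_labels(incomplete, ref)


class TestMapBack:
    def test_roundtrip_and_angle_preservation(self, small_scene):
        _, micrograph, _ = small_scene
        box = BoundingBox(300, 400, 64, 64)
        (crop,) = crop_particles(micrograph, [box])
        pose = hinge_pose("p", HINGE, (20, 150), (100, 100), (170, 40))
        mapped = map_pose_to_micrograph(pose, crop)
        assert mapped.angle() == pytest.approx(pose.angle(), abs=1e-9)
        for name in ANGLE_POINTS:
            back = crop.to_crop(mapped.get(name))
            assert back.x == pytest.approx(pose.get(name).x, abs=1e-9)
            assert back.y == pytest.approx(pose.get(name).y, abs=1e-9)

    def test_missing_provenance_raises(self):
        pose = hinge_pose("p", HINGE, (0, 1), (0, 0), (1, 0))
        with pytest.raises(ValueError):
            map_pose_to_micrograph(pose, None)
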