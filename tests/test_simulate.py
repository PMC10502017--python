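import numpy as np
import pytest

from origamiflex import (
    AngleLaw,
    Micrograph,
    Point2D,
    SimulationConfig,
    angle_at_vertex,
    generate_dataset,
    generate_micrograph,
    render_hinge,
    sample_angles,
)
from origamiflex.io import read_yolo_labels
from origamiflex.mechanics import ks_two_sample


class TestAngleLaws:
    def test_zero_samples(self):
        assert sample_angles(AngleLaw.uniform(), 0, 1).size == 0

    def test_degenerate_gaussian(self):
        out = sample_angles(AngleLaw.gaussian(90.0, 0.0), 5, 1)
        assert np.array_equal(out, np.full(5, 90.0))

    def test_truncated_gaussian_mean_within_clt_bound(self):
        n = 10_000
        out = sample_angles(AngleLaw.truncated_gaussian(90.0, 15.0), n, 5)
        assert abs(out.mean() - 90.0) <= 3 * 15.0 / np.sqrt(n)

    def test_support_is_respected(self):
        for law in (
            AngleLaw.uniform(30, 60),
            AngleLaw.gaussian(90, 40),
            AngleLaw.truncated_gaussian(170, 30, low=10, high=175),
            AngleLaw.empirical([0, 90, 180], [0.25, 0.75]),
        ):
            out = sample_angles(law, 2000, 9)
            assert out.min() >= 0.0 and out.max() <= 180.0

    def test_reproducible_under_seed(self):
        law = AngleLaw.truncated_gaussian(90, 15)
        assert np.array_equal(sample_angles(law, 100, 42), sample_angles(law, 100, 42))

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            AngleLaw.uniform(-5, 50)
        with pytest.raises(ValueError):
            AngleLaw.gaussian(90, -1)
        with pytest.raises(ValueError):
            AngleLaw.empirical([0, 90], [0.5, 0.5])

    def test_distribution_fidelity_two_independent_samples(self):
        """Two independent draws from one law are KS-indistinguishable."""
        law = AngleLaw.truncated_gaussian(90.0, 15.0)
        a = sample_angles(law, 10_000, 101)
        b = sample_angles(law, 10_000, 202)
        _, p = ks_two_sample(a, b)
        assert p > 0.01

    def test_roundtrip_serialization(self):
        for law in (
            AngleLaw.uniform(10, 20),
            AngleLaw.gaussian(80, 5),
            AngleLaw.truncated_gaussian(90, 15, 30, 150),
            AngleLaw.empirical([0, 60, 180], [0.5, 0.5]),
        ):
            assert AngleLaw.from_dict(law.to_dict()) == law


class TestRenderHinge:
    def _blank_canvas(self, config):
        return Micrograph(
            pixels=np.full((config.image_size, config.image_size),
                           config.background_level),
            nm_per_px=config.nm_per_px,
        )

    @pytest.mark.parametrize("rotation", [0.0, 137.0])
    def test_true_angle_recomputes_regardless_of_rotation(self, rotation):
        config = SimulationConfig()
        canvas = self._blank_canvas(config)
        record = render_hinge(canvas, 90.0, rotation, Point2D(480, 480), config)
        pose = record.true_pose
        recomputed = angle_at_vertex(
            pose.get("tip_a"), pose.get("vertex"), pose.get("tip_b")
        )
        assert recomputed == pytest.approx(90.0, abs=1e-6)
        assert record.true_angle == pytest.approx(90.0, abs=1e-6)

    def test_particle_pixels_brighter_than_background(self):
        config = SimulationConfig()
        canvas = self._blank_canvas(config)
        record = render_hinge(canvas, 95.0, 30.0, Point2D(300, 300), config)
        box = record.true_box
        region = canvas.pixels[
            int(box.y_min) : int(box.y_max), int(box.x_min) : int(box.x_max)
        ]
        particle = region[region > config.background_level + 0.01]
        assert particle.size > 0
        assert particle.mean() >= config.background_level + config.particle_intensity / 2

    def test_box_contains_all_keypoints(self):
        config = SimulationConfig()
        canvas = self._blank_canvas(config)
        record = render_hinge(canvas, 120.0, 45.0, Point2D(200, 700), config)
        for name in ("tip_a", "vertex", "tip_b"):
            assert record.true_box.contains_point(record.true_pose.get(name), tol=1e-6)

    def test_out_of_canvas_raises(self):
        config = SimulationConfig()
        canvas = self._blank_canvas(config)
        with pytest.raises(ValueError):
            render_hinge(canvas, 90.0, 0.0, Point2D(10, 10), config)


class TestGenerateMicrograph:
    def test_empty_scene_matches_background_model(self):
        config = SimulationConfig(
            seed=1, n_target_hinges=0, n_vertical_distractors=0,
            n_aggregates=0, n_free_blobs=0, n_boundary_fragments=0,
        )
        micrograph, records = generate_micrograph(config)
        assert records == []
        assert abs(micrograph.pixels.mean() - config.background_level) < 0.02
        assert micrograph.pixels.std() < 3 * (config.noise_sd + config.mottle_sd)

    def test_counts_are_conserved(self, small_scene):
        config, _, records = small_scene
        by_class = {}
        for r in records:
            by_class[r.particle_class] = by_class.get(r.particle_class, 0) + 1
        assert by_class["target_hinge"] == config.n_target_hinges
        assert by_class["vertical_distractor"] == config.n_vertical_distractors
        assert by_class["aggregate"] == config.n_aggregates
        assert by_class["blob"] == config.n_free_blobs
        assert by_class["boundary_fragment"] == config.n_boundary_fragments

    def test_angle_recovery_at_source(self, small_scene):
        """Every target's keypoints reproduce its sampled angle exactly."""
        _, _, records = small_scene
        for r in records:
            if r.particle_class != "target_hinge":
                assert r.true_pose is None
                continue
            pose = r.true_pose
            recomputed = angle_at_vertex(
                pose.get("tip_a"), pose.get("vertex"), pose.get("tip_b")
            )
            assert recomputed == pytest.approx(r.true_angle, abs=1e-6)
            for name in pose.schema.keypoint_names:
                assert r.true_box.contains_point(pose.get(name), tol=1e-6)

    def test_deterministic_bytes_under_seed(self):
        config = SimulationConfig(seed=77, image_size=480, n_target_hinges=5,
                                  n_vertical_distractors=1, n_aggregates=1,
                                  n_free_blobs=2, n_boundary_fragments=1)
        m1, r1 = generate_micrograph(config)
        m2, r2 = generate_micrograph(config)
        assert m1.pixels.tobytes() == m2.pixels.tobytes()
        assert [r.particle_id for r in r1] == [r.particle_id for r in r2]
        assert all(
            a.true_box == b.true_box and a.true_angles == b.true_angles
            for a, b in zip(r1, r2)
        )

    def test_impossible_placement_reports_achieved_count(self):
        config = SimulationConfig(
            seed=0, image_size=250, n_target_hinges=30, max_place_attempts=20,
            n_vertical_distractors=0, n_aggregates=0, n_free_blobs=0,
            n_boundary_fragments=0,
        )
        with pytest.raises(RuntimeError, match="placed"):
            generate_micrograph(config)

    def test_steridyn_targets_have_two_angles(self):
        config = SimulationConfig(seed=5, device="steridyn", n_target_hinges=3,
                                  n_vertical_distractors=0, n_aggregates=0,
                                  n_free_blobs=0, n_boundary_fragments=0)
        _, records = generate_micrograph(config)
        for r in records:
            assert len(r.true_angles) == 2
            assert r.true_pose.angles() == pytest.approx(r.true_angles, abs=1e-6)


class TestGenerateDataset:
    def test_empty_dataset(self, tmp_path):
        manifest = generate_dataset(SimulationConfig(seed=1), 0, tmp_path)
        assert manifest["images"] == []

    def test_files_and_label_roundtrip(self, tmp_path):
        config = SimulationConfig(seed=9, image_size=480, n_target_hinges=4,
                                  n_vertical_distractors=1, n_aggregates=0,
                                  n_free_blobs=1, n_boundary_fragments=1)
        manifest = generate_dataset(config, 3, tmp_path)
        assert len(manifest["images"]) == 3
        for entry in manifest["images"]:
            assert (tmp_path / entry["image"]).exists()
            boxes = read_yolo_labels(tmp_path / entry["labels"], config.image_size)
            assert len(boxes) == entry["n_targets"] == config.n_target_hinges
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "ground_truth_keypoints.csv").exists()

    def test_labels_roundtrip_exactly(self, tmp_path):
        """Boxes written as YOLO labels read back to the same pixels."""
        config = SimulationConfig(seed=2, image_size=960, n_target_hinges=3,
                                  n_vertical_distractors=0, n_aggregates=0,
                                  n_free_blobs=0, n_boundary_fragments=0)
        generate_dataset(config, 1, tmp_path)
        from origamiflex.simulate import generate_micrograph as gen
        import json

        manifest = json.loads((tmp_path / "manifest.json").read_text())
        image_config = SimulationConfig.from_dict(
            {**config.to_dict(), "seed": manifest["images"][0]["seed"]}
        )
        _, records = gen(image_config)
        targets = [r for r in records if r.particle_class == "target_hinge"]
        boxes = read_yolo_labels(tmp_path / manifest["images"][0]["labels"], 960)
        for box, record in zip(boxes, targets):
            assert box.cx == pytest.approx(record.true_box.cx, abs=1e-2)
            assert box.w == pytest.approx(record.true_box.w, abs=1e-2)
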