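"""Synthetic swallow scenes: kinematics, rendering, dataset determinism."""

import numpy as np
import pytest

from sdstrack.geometry import backproject_array, project_array
from sdstrack.synthetic import (AMPLITUDE_MEAN, AMPLITUDE_SD, DatasetConfig,
                                SceneParams, TrajectoryParams,
                                default_meta, draw_subject_amplitudes,
                                generate_trajectory, make_dataset,
                                render_sequence, scene_depth)


class TestGenerateTrajectory:
    def test_zero_amplitude_zero_jitter_is_constant(self):
        params = TrajectoryParams(amp_lr=0, amp_cc=0, amp_ap=0, jitter_sd=0)
        _, points, _ = generate_trajectory(params, fps=30, duration=15)
        assert np.ptp(points, axis=0) == pytest.approx((0, 0, 0))

    def test_cc_range_equals_amplitude_exactly(self):
        params = TrajectoryParams(amp_lr=0, amp_cc=20.0, amp_ap=0, jitter_sd=0)
        _, points, _ = generate_trajectory(params, fps=60, duration=15)
        assert np.ptp(points[:, 1]) == pytest.approx(20.0, abs=1e-9)

    def test_all_axis_ranges_equal_amplitudes_noise_free(self):
        params = TrajectoryParams(amp_lr=2.0, amp_cc=21.4, amp_ap=6.4,
                                  jitter_sd=0)
        _, points, _ = generate_trajectory(params, fps=60, duration=15)
        ranges = np.ptp(points, axis=0)
        # CC/AP pulse peaks land on the frame grid; the lateral wobble peaks
        # at quarter phase, between samples, so LR is exact only to ~0.5%
        assert ranges[1:] == pytest.approx((21.4, 6.4), abs=1e-9)
        assert ranges[0] == pytest.approx(2.0, rel=5e-3)

    def test_cc_range_with_jitter_over_seeds(self):
        """Monte-Carlo: jitter (0.2 mm SD) inflates the 20 mm CC range by
        well under 1 mm on average."""
        ranges = []
        for seed in range(50):
            params = TrajectoryParams(amp_cc=20.0, jitter_sd=0.2, seed=seed)
            _, points, _ = generate_trajectory(params, fps=30, duration=15)
            ranges.append(np.ptp(points[:, 1]))
        assert np.mean(ranges) == pytest.approx(20.0, abs=1.0)

    def test_events_mark_each_swallow(self):
        params = TrajectoryParams(jitter_sd=0)
        times, points, events = generate_trajectory(params, fps=30, duration=15)
        assert len(events) == 3
        for ev in events:
            assert ev["start"] < ev["peak"] < ev["end"]
            # CC excursion is maximal (most negative camera Y) at the peak
            assert points[ev["peak"], 1] == pytest.approx(-21.4, abs=0.05)

    def test_too_short_duration_names_minimum(self):
        params = TrajectoryParams()
        with pytest.raises(ValueError, match="13.5"):
            generate_trajectory(params, fps=30, duration=5.0)

    def test_trajectory_is_smooth(self):
        """No frame-to-frame jump exceeds what the pulse slope allows."""
        params = TrajectoryParams(jitter_sd=0)
        _, points, _ = generate_trajectory(params, fps=60, duration=15)
        step = np.abs(np.diff(points[:, 1]))
        # max slope of amp*raised_cosine is amp*pi/swallow_duration
        assert step.max() <= 21.4 * np.pi / 1.5 / 60 * 1.01


class TestRenderSequence:
    def test_static_trajectory_gives_identical_labels(self):
        meta = default_meta()
        scene = SceneParams(depth_noise_sd=0.0)
        rest = (0.0, 0.0, scene.neck_distance - scene.bump_height)
        times = np.arange(5) / meta.fps
        points = np.tile(rest, (5, 1))
        frames, labels = render_sequence(times, points, scene, meta)
        assert len(labels) == 5
        assert len({(l.x, l.y) for l in labels}) == 1

    def test_bump_protrudes_toward_camera(self):
        meta = default_meta()
        scene = SceneParams(depth_noise_sd=0.0)
        rest = (0.0, 0.0, scene.neck_distance - scene.bump_height)
        frames, labels = render_sequence(np.array([0.0]), np.array([rest]),
                                         scene, meta)
        depth = frames[0].depth
        lab = labels[0]
        assert depth[int(lab.y), int(lab.x)] < depth[2, 2]

    def test_noise_free_depth_at_label_matches_closed_form(self):
        """At rest the apex depth equals neck standoff minus bump height.

        Uses an integer principal point so the resting label falls exactly
        on a pixel centre (the closed form holds at the continuous label
        coordinate)."""
        from sdstrack.geometry import CameraIntrinsics
        from sdstrack.rgbd_io import SequenceMeta
        meta = SequenceMeta(fps=30, width=256, height=256,
                            intrinsics=CameraIntrinsics(300, 300, 128.0, 128.0),
                            depth_unit_scale=0.1)
        scene = SceneParams(depth_noise_sd=0.0)
        rest = (0.0, 0.0, scene.neck_distance - scene.bump_height)
        frames, labels = render_sequence(np.array([0.0]), np.array([rest]),
                                         scene, meta)
        lab = labels[0]
        got = frames[0].depth[int(round(lab.y)), int(round(lab.x))]
        assert got == pytest.approx(scene.neck_distance - scene.bump_height,
                                    abs=0.01)

    def test_rendered_depth_equals_analytic_scene_everywhere(self):
        meta = default_meta()
        scene = SceneParams(depth_noise_sd=0.0)
        point = (3.0, -10.0, scene.neck_distance - scene.bump_height - 4.0)
        frames, _ = render_sequence(np.array([0.0]), np.array([point]),
                                    scene, meta)
        px, py = np.meshgrid(np.arange(meta.width, dtype=float),
                             np.arange(meta.height, dtype=float))
        analytic = scene_depth(px, py, np.asarray(point), scene, meta.intrinsics)
        np.testing.assert_allclose(frames[0].depth, analytic, atol=0.01)

    def test_labels_backproject_to_input_trajectory(self):
        """Noise-free: label pixels + rendered depths recover the simulated
        world trajectory to well under 0.5 mm."""
        meta = default_meta()
        scene = SceneParams(depth_noise_sd=0.0)
        params = TrajectoryParams(jitter_sd=0)
        rest = (0.0, 0.0, scene.neck_distance - scene.bump_height)
        times, points, _ = generate_trajectory(params, meta.fps, 15.0, rest=rest)
        frames, labels = render_sequence(times, points, scene, meta)
        assert len(labels) == len(frames)
        pixels = np.array([[l.x, l.y] for l in labels])
        depths = np.array([frames[l.frame_index].depth[int(round(l.y)),
                                                       int(round(l.x))]
                           for l in labels])
        recovered = backproject_array(pixels, depths, meta.intrinsics)
        err = np.abs(recovered - points).max()
        assert err <= 0.5

    def test_occlusion_band_masks_top_rows(self):
        meta = default_meta()
        base = SceneParams(depth_noise_sd=0.0)
        occluded = SceneParams(depth_noise_sd=0.0, occlude_top_px=40)
        rest = np.array([(0.0, 0.0, 394.0)])
        f0, _ = render_sequence(np.array([0.0]), rest, base, meta)
        f1, _ = render_sequence(np.array([0.0]), rest, occluded, meta)
        assert np.all(f1[0].depth[:40] == occluded.neck_distance - 80.0)
        np.testing.assert_array_equal(f0[0].depth[40:], f1[0].depth[40:])

    def test_out_of_frame_prominence_label_omitted(self):
        meta = default_meta()
        scene = SceneParams(depth_noise_sd=0.0)
        ok = (0.0, 0.0, 394.0)
        off = (500.0, 0.0, 394.0)     # projects far outside the image
        frames, labels = render_sequence(np.array([0.0, 1 / 30.0]),
                                         np.array([ok, off]), scene, meta)
        assert len(frames) == 2
        assert [l.frame_index for l in labels] == [0]


class TestMakeDataset:
    def test_split_counts_and_determinism(self, tmp_path):
        config = DatasetConfig(n_subjects=3, n_train=2, duration=5.0, seed=9,
                               trajectory=TrajectoryParams(n_swallows=1,
                                                           rest_duration=1.0),
                               reduced=True)
        m1 = make_dataset(config, tmp_path / "a")
        m2 = make_dataset(config, tmp_path / "b")
        splits = [s["split"] for s in m1["subjects"]]
        assert splits == ["train", "train", "validation"]
        # same master seed -> byte-identical artifacts
        for sub in m1["subjects"]:
            for f in sorted((tmp_path / "a" / sub["path"]).iterdir()):
                twin = tmp_path / "b" / sub["path"] / f.name
                assert f.read_bytes() == twin.read_bytes(), f.name
        assert (tmp_path / "a" / "manifest.yaml").read_bytes() == \
               (tmp_path / "b" / "manifest.yaml").read_bytes()

    def test_amplitude_draws_truncated_at_zero(self):
        rng = np.random.default_rng(123)
        draws = [draw_subject_amplitudes(rng) for _ in range(1000)]
        for ax in ("lr", "cc", "ap"):
            values = np.array([d[ax] for d in draws])
            assert (values >= 0).all()
            # distribution centred near the cohort mean
            assert np.mean(values) == pytest.approx(
                AMPLITUDE_MEAN[ax], abs=4 * AMPLITUDE_SD[ax] / np.sqrt(1000) +
                0.2 * AMPLITUDE_SD[ax])
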