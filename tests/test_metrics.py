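"""Motion-range statistics: per-recording ranges, cohort summary, repeats."""

import numpy as np
import pytest

from sdstrack.geometry import CameraIntrinsics
from sdstrack.metrics import (MotionSummary, Trajectory3D, camera_to_anatomical,
                              cohort_summary, exceedance_curve, motion_summary,
                              reproducibility_summary, summaries_to_frame,
                              trajectory_from_predictions)
from sdstrack.pose import Prediction

# Published per-patient motion measurements (LR, CC, AP, Distance), mm.
PATIENT_MOTION = [
    (2.0, 16.0, 3.0, 16.4),
    (1.7, 29.9, 5.6, 30.5),
    (2.5, 24.6, 3.9, 25.0),
    (1.6, 16.4, 10.5, 19.5),
    (1.3, 17.5, 5.5, 18.4),
    (0.1, 23.2, 4.6, 23.7),
    (2.0, 22.5, 11.5, 25.3),
]


def traj_with_ranges(lr, cc, ap, source_id=""):
    """Two-point anatomical trajectory whose per-axis ranges are (lr, cc, ap)."""
    points = np.array([[0.0, 0.0, 0.0], [lr, cc, ap]])
    return Trajectory3D(times=np.array([0.0, 1.0]), points=points,
                        source_id=source_id)


class TestMotionSummary:
    @pytest.mark.parametrize("lr,cc,ap,distance", PATIENT_MOTION)
    def test_spatial_displacement_matches_published_rows(self, lr, cc, ap,
                                                         distance):
        s = motion_summary(traj_with_ranges(lr, cc, ap))
        assert round(s.spatial_displacement, 1) == distance
        assert (s.lr_range, s.cc_range, s.ap_range) == (lr, cc, ap)

    def test_zero_motion(self):
        s = motion_summary(traj_with_ranges(0, 0, 0))
        assert s.spatial_displacement == 0.0

    def test_displacement_dominates_each_axis(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pts = rng.normal(0, 5, size=(20, 3))
            traj = Trajectory3D(times=np.arange(20.0), points=pts)
            s = motion_summary(traj)
            assert s.spatial_displacement >= max(s.lr_range, s.cc_range,
                                                 s.ap_range) - 1e-12

    def test_invariant_under_time_reversal_and_translation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 5, size=(30, 3))
        t = np.arange(30.0)
        s1 = motion_summary(Trajectory3D(times=t, points=pts))
        s2 = motion_summary(Trajectory3D(times=t, points=pts[::-1] + 100.0))
        for attr in ("lr_range", "cc_range", "ap_range", "spatial_displacement"):
            assert getattr(s1, attr) == pytest.approx(getattr(s2, attr),
                                                      rel=1e-12)

    def test_requires_two_points(self):
        traj = Trajectory3D(times=np.array([0.0]), points=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            motion_summary(traj)

    def test_median_smoothing_shrinks_spike_driven_range(self):
        pts = np.zeros((31, 3))
        pts[15, 1] = 10.0    # single-frame spike
        traj = Trajectory3D(times=np.arange(31.0), points=pts)
        assert motion_summary(traj).cc_range == 10.0
        assert motion_summary(traj, smooth_window=5).cc_range == 0.0


class TestCohortSummary:
    def test_reproduces_published_cohort_row(self):
        """The seven printed per-patient triples give every Mean +/- SD cell:
        1.6 +/- 0.8, 21.4 +/- 5.1, 6.4 +/- 3.3, 22.7 +/- 4.9 (sample SD)."""
        summaries = [motion_summary(traj_with_ranges(lr, cc, ap))
                     for lr, cc, ap, _ in PATIENT_MOTION]
        stats = cohort_summary(summaries)
        assert (round(stats["lr_range"].mean, 1),
                round(stats["lr_range"].sd, 1)) == (1.6, 0.8)
        assert (round(stats["cc_range"].mean, 1),
                round(stats["cc_range"].sd, 1)) == (21.4, 5.1)
        assert (round(stats["ap_range"].mean, 1),
                round(stats["ap_range"].sd, 1)) == (6.4, 3.3)
        assert (round(stats["spatial_displacement"].mean, 1),
                round(stats["spatial_displacement"].sd, 1)) == (22.7, 4.9)

    def test_identical_inputs_sd_zero(self):
        s = motion_summary(traj_with_ranges(1, 2, 3))
        stats = cohort_summary([s, s, s])
        assert stats["cc_range"].sd == 0.0

    def test_single_recording_errors(self):
        with pytest.raises(ValueError):
            cohort_summary([motion_summary(traj_with_ranges(1, 2, 3))])

    def test_table_rendering_includes_cohort_row(self):
        summaries = [motion_summary(traj_with_ranges(lr, cc, ap))
                     for lr, cc, ap, _ in PATIENT_MOTION]
        df = summaries_to_frame(summaries)
        assert list(df.columns) == ["subject", "LR (mm)", "CC (mm)",
                                    "AP (mm)", "Distance (mm)"]
        assert df.iloc[-1]["CC (mm)"] == "21.4 ± 5.1"
        assert df.iloc[-1]["Distance (mm)"] == "22.7 ± 4.9"


class TestTrajectoryFromPredictions:
    def test_constant_prediction_constant_trajectory(self, intrinsics):
        preds = [Prediction(i, 100.0, 80.0, 400.0) for i in range(5)]
        traj = trajectory_from_predictions(preds, intrinsics, fps=30)
        assert np.ptp(traj.points, axis=0) == pytest.approx((0, 0, 0))

    def test_principal_point_maps_to_axis_origin(self, intrinsics):
        preds = [Prediction(i, intrinsics.cx, intrinsics.cy, 400.0)
                 for i in range(3)]
        traj = trajectory_from_predictions(preds, intrinsics, fps=30)
        assert traj.points[:, 0] == pytest.approx(0.0)   # LR
        assert traj.points[:, 1] == pytest.approx(0.0)   # CC

    def test_anatomical_axis_signs(self, intrinsics):
        """Image-up motion is cranial (+CC); decreasing depth is anterior (+AP)."""
        preds = [Prediction(0, intrinsics.cx, intrinsics.cy, 400.0),
                 Prediction(1, intrinsics.cx, intrinsics.cy - 30.0, 399.0),
                 Prediction(2, intrinsics.cx, intrinsics.cy, 400.0)]
        traj = trajectory_from_predictions(preds, intrinsics, fps=30)
        assert traj.points[1, 1] > 0      # CC positive at the raised frame
        assert traj.points[1, 2] > 0      # AP positive toward the camera

    def test_invalid_predictions_skipped(self, intrinsics):
        preds = [Prediction(0, 10, 10, 400.0),
                 Prediction(1, 10, 10, 0.0, valid=False),
                 Prediction(2, 10, 10, 400.0)]
        traj = trajectory_from_predictions(preds, intrinsics, fps=30)
        assert len(traj.times) == 2

    def test_fewer_than_two_valid_errors(self, intrinsics):
        with pytest.raises(ValueError):
            trajectory_from_predictions([Prediction(0, 1, 1, 100.0)],
                                        intrinsics, fps=30)


class TestCameraToAnatomical:
    def test_round_trip_ranges_preserved(self):
        rng = np.random.default_rng(2)
        cam = rng.normal([0, 0, 400], [2, 10, 3], size=(50, 3))
        anat = camera_to_anatomical(cam)
        np.testing.assert_allclose(np.ptp(anat, axis=0), np.ptp(cam, axis=0))


class TestReproducibility:
    def test_identical_repeats_sd_zero(self):
        s = motion_summary(traj_with_ranges(1.6, 21.4, 6.4))
        df = reproducibility_summary({"subj": [s, s, s]})
        assert df.iloc[0]["cc_sd"] == pytest.approx(0.0, abs=1e-12)
        assert df.iloc[0]["n_repeats"] == 3

    def test_hand_computed_repeat_stats(self):
        repeats = [motion_summary(traj_with_ranges(1.0, cc, 3.0))
                   for cc in (20.0, 21.0, 22.0)]
        df = reproducibility_summary({"s1": repeats})
        assert df.iloc[0]["cc_mean"] == pytest.approx(21.0)
        assert df.iloc[0]["cc_sd"] == pytest.approx(1.0)

    def test_single_repeat_subject_skipped(self):
        s = motion_summary(traj_with_ranges(1, 2, 3))
        df = reproducibility_summary({"a": [s, s], "b": [s]})
        assert list(df["subject"]) == ["a"]


def test_exceedance_curve_monotone():
    rng = np.random.default_rng(3)
    traj = Trajectory3D(times=np.arange(100.0),
                        points=rng.normal(0, 5, size=(100, 3)))
    curve = exceedance_curve(traj)
    assert curve["time_fraction"].iloc[0] == 1.0
    assert (np.diff(curve["time_fraction"]) <= 1e-12).all()
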