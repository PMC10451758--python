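"""Motion-range statistics of tracked laryngeal trajectories.

Tracked pixel predictions are back-projected to metric camera coordinates
and mapped onto anatomical axes for the supine, camera-facing setup:

    LR (left-right)       =  camera X
    CC (cranio-caudal)    = -camera Y   (image up = cranial)
    AP (anterior-post.)   = -(Z - resting median depth)   (toward camera = anterior)

For each recording the per-axis motion range is the max-minus-min of that
coordinate over the trajectory, and the spatial displacement is the
Euclidean norm of the three ranges.  Cohort summaries report mean and
sample SD (n-1); repeat-measurement tables quantify within-subject
variability over consecutive recordings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .geometry import CameraIntrinsics, backproject_array
from .pose import Prediction

__all__ = ["Trajectory3D", "MotionSummary", "SummaryStat",
           "trajectory_from_predictions", "camera_to_anatomical",
           "motion_summary", "cohort_summary", "reproducibility_summary",
           "summaries_to_frame", "exceedance_curve"]

logger = logging.getLogger(__name__)

AXES = ("lr", "cc", "ap")


@dataclass
class Trajectory3D:
    """Time series of 3D positions (mm).

    ``frame`` records the coordinate convention of ``points``: "camera"
    (X right, Y down, Z depth) or "anatomical" (LR, CC, AP).
    """

    times: np.ndarray
    points: np.ndarray
    source_id: str = ""
    frame: str = "anatomical"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (len(self.times), 3):
            raise ValueError("points must have shape (n_times, 3)")
        if len(self.times) >= 2 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = ["lr", "cc", "ap"] if self.frame == "anatomical" else ["X", "Y", "Z"]
        df = pd.DataFrame(self.points, columns=cols)
        df.insert(0, "t", self.times)
        return df


@dataclass(frozen=True)
class MotionSummary:
    """Per-axis motion ranges and spatial displacement of one recording, mm."""

    lr_range: float
    cc_range: float
    ap_range: float
    spatial_displacement: float
    n_frames_used: int = 0
    source_id: str = ""

    @classmethod
    def from_ranges(cls, lr: float, cc: float, ap: float,
                    n_frames_used: int = 0, source_id: str = "") -> "MotionSummary":
        return cls(lr, cc, ap, math.sqrt(lr * lr + cc * cc + ap * ap),
                   n_frames_used, source_id)


@dataclass(frozen=True)
class SummaryStat:
    """Mean and sample SD (n-1 denominator) of one field over a cohort."""

    mean: float
    sd: float
    n: int


def camera_to_anatomical(points: np.ndarray,
                         rest_depth: float | None = None) -> np.ndarray:
    """Map camera-frame (X, Y, Z) mm to anatomical (LR, CC, AP) mm.

    ``rest_depth`` is the resting optical-axis depth; it defaults to the
    median Z of the trajectory (the patient rests for most of a recording).
    """
    points = np.asarray(points, dtype=float)
    if rest_depth is None:
        rest_depth = float(np.median(points[:, 2]))
    out = np.empty_like(points)
    out[:, 0] = points[:, 0]
    out[:, 1] = -points[:, 1]
    out[:, 2] = -(points[:, 2] - rest_depth)
    return out


def trajectory_from_predictions(preds: list[Prediction],
                                intrinsics: CameraIntrinsics,
                                fps: float, source_id: str = "") -> Trajectory3D:
    """Back-project tracked predictions into an anatomical trajectory.

    Invalid predictions (no depth) are skipped; fewer than two valid
    predictions raise a ValueError.
    """
    valid = [p for p in preds if p.valid and p.depth_mm > 0]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid predictions for a trajectory")
    pixels = np.array([[p.x, p.y] for p in valid])
    depths = np.array([p.depth_mm for p in valid])
    cam = backproject_array(pixels, depths, intrinsics)
    anatomical = camera_to_anatomical(cam)
    times = np.array([p.frame_index for p in valid], dtype=float) / fps
    return Trajectory3D(times=times, points=anatomical, source_id=source_id,
                        frame="anatomical")


def motion_summary(traj: Trajectory3D,
                   smooth_window: int | None = None) -> MotionSummary:
    """Per-axis motion range (max - min) and spatial displacement.

    ``smooth_window`` optionally applies an odd-width temporal median
    filter per axis before taking extrema; the default (None) matches the
    raw extremum procedure, since smoothing changes range statistics.
    """
    if traj.frame != "anatomical":
        raise ValueError("motion_summary expects an anatomical-frame trajectory; "
                         "apply camera_to_anatomical first")
    pts = traj.points
    if len(pts) < 2:
        raise ValueError("need at least 2 points for a motion range")
    if smooth_window is not None:
        if smooth_window % 2 != 1 or smooth_window < 3:
            raise ValueError("smooth_window must be an odd integer >= 3")
        pts = np.column_stack([medfilt(pts[:, i], smooth_window) for i in range(3)])
    ranges = np.ptp(pts, axis=0)
    return MotionSummary.from_ranges(float(ranges[0]), float(ranges[1]),
                                     float(ranges[2]), n_frames_used=len(pts),
                                     source_id=traj.source_id)


def cohort_summary(summaries: list[MotionSummary]) -> dict[str, SummaryStat]:
    """Cohort mean +/- sample SD of each motion field."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 recordings for a cohort summary")
    fields = {"lr_range": [s.lr_range for s in summaries],
              "cc_range": [s.cc_range for s in summaries],
              "ap_range": [s.ap_range for s in summaries],
              "spatial_displacement": [s.spatial_displacement for s in summaries]}
    return {name: SummaryStat(mean=float(np.mean(v)),
                              sd=float(np.std(v, ddof=1)), n=len(v))
            for name, v in fields.items()}


def summaries_to_frame(summaries: list[MotionSummary],
                       with_cohort_row: bool = True) -> pd.DataFrame:
    """Tabulate recordings as columns (subject, LR, CC, AP, Distance), mm.

    Values are rounded to 1 decimal; with ``with_cohort_row`` a final
    "Mean ± SD" row is appended.
    """
    rows = [{"subject": s.source_id or str(i + 1),
             "LR (mm)": round(s.lr_range, 1),
             "CC (mm)": round(s.cc_range, 1),
             "AP (mm)": round(s.ap_range, 1),
             "Distance (mm)": round(s.spatial_displacement, 1)}
            for i, s in enumerate(summaries)]
    if with_cohort_row and len(summaries) >= 2:
        stats = cohort_summary(summaries)
        rows.append({
            "subject": "Mean ± SD",
            "LR (mm)": f"{stats['lr_range'].mean:.1f} ± {stats['lr_range'].sd:.1f}",
            "CC (mm)": f"{stats['cc_range'].mean:.1f} ± {stats['cc_range'].sd:.1f}",
            "AP (mm)": f"{stats['ap_range'].mean:.1f} ± {stats['ap_range'].sd:.1f}",
            "Distance (mm)": (f"{stats['spatial_displacement'].mean:.1f} ± "
                              f"{stats['spatial_displacement'].sd:.1f}"),
        })
    return pd.DataFrame(rows)


def reproducibility_summary(repeats: dict[str, list[MotionSummary]]
                            ) -> pd.DataFrame:
    """Within-subject variability over consecutive repeat measurements.

    One row per subject with >= 2 repeats: mean and sample SD of each
    motion field across that subject's repeats.  Subjects with a single
    repeat are skipped with a warning.
    """
    rows = []
    for subject, summaries in repeats.items():
        if len(summaries) < 2:
            logger.warning("subject %s has %d repeat(s); skipped",
                           subject, len(summaries))
            continue
        row = {"subject": subject, "n_repeats": len(summaries)}
        for name, values in (
                ("lr", [s.lr_range for s in summaries]),
                ("cc", [s.cc_range for s in summaries]),
                ("ap", [s.ap_range for s in summaries]),
                ("distance", [s.spatial_displacement for s in summaries])):
            row[f"{name}_mean"] = float(np.mean(values))
            row[f"{name}_sd"] = float(np.std(values, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def exceedance_curve(traj: Trajectory3D, n_thresholds: int = 100
                     ) -> pd.DataFrame:
    """Fraction of recording time spent at or beyond each displacement.

    Displacement per frame is the Euclidean distance from the resting
    position (per-axis median).  A diagnostic for choosing individualised
    margins short of the full extremum.
    """
    rest = np.median(traj.points, axis=0)
    disp = np.linalg.norm(traj.points - rest, axis=1)
    thresholds = np.linspace(0.0, float(disp.max()), n_thresholds)
    frac = [(disp >= d).mean() for d in thresholds]
    return pd.DataFrame({"displacement_mm": thresholds, "time_fraction": frac})
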