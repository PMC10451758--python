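"""Synthetic swallowing scenes: RGBD videos with ground-truth labels.

The generator stands in for the clinical recording protocol: a supine
patient faces the depth camera, a cross marker sits on the resting
laryngeal prominence, and the patient swallows three times consecutively.
Geometry is a neck-like cylindrical background surface bearing a Gaussian
bump (the prominence) that executes smooth raised-cosine swallow
excursions — large cranio-caudal travel, moderate anterior travel, and a
small lateral wobble — with per-frame Gaussian jitter and sensor depth
noise.  Default per-axis amplitudes are the cohort means of the clinical
motion measurements (LR 1.6 mm, CC 21.4 mm, AP 6.4 mm).

Every rendered frame comes with its exact ground-truth pixel label
(forward projection of the prominence) and the world trajectory is saved
alongside each sequence, so tracking error can be measured end to end.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .geometry import CameraIntrinsics, project_array
from .rgbd_io import PointLabel, RGBDFrame, SequenceMeta, write_labels, write_sequence

__all__ = ["TrajectoryParams", "SceneParams", "DatasetConfig",
           "generate_trajectory", "render_sequence", "make_dataset",
           "default_meta", "reduced_meta", "reduced_dataset_config",
           "load_trajectory_csv"]

logger = logging.getLogger(__name__)

# Cohort mean +/- SD of the measured per-axis motion ranges (mm), used both
# as default amplitudes and for per-subject amplitude draws.
AMPLITUDE_MEAN = {"lr": 1.6, "cc": 21.4, "ap": 6.4}
AMPLITUDE_SD = {"lr": 0.8, "cc": 5.1, "ap": 3.3}


@dataclass(frozen=True)
class TrajectoryParams:
    """Kinematic parameters of the simulated swallow sequence.

    Amplitudes are peak excursions in mm and equal the per-axis
    max-minus-min range of the noise-free trajectory by construction.
    """

    n_swallows: int = 3
    amp_lr: float = AMPLITUDE_MEAN["lr"]
    amp_cc: float = AMPLITUDE_MEAN["cc"]
    amp_ap: float = AMPLITUDE_MEAN["ap"]
    swallow_duration: float = 1.5   # s
    rest_duration: float = 3.0      # s, before each swallow
    jitter_sd: float = 0.2          # mm, per-frame Gaussian on all axes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_swallows < 1:
            raise ValueError("n_swallows must be >= 1")
        if min(self.amp_lr, self.amp_cc, self.amp_ap) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.swallow_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be > 0")

    @property
    def min_duration(self) -> float:
        return self.n_swallows * (self.swallow_duration + self.rest_duration)


@dataclass(frozen=True)
class SceneParams:
    """Physical stand-in for the anterior neck surface.

    The background is a vertical cylinder (axis cranio-caudal) of radius
    ``neck_radius`` whose nearest line sits ``neck_distance`` mm from the
    camera; the prominence is a Gaussian bump of height ``bump_height`` and
    footprint ``bump_sigma`` protruding toward the camera.
    """

    neck_radius: float = 60.0       # mm
    neck_distance: float = 400.0    # mm, camera-to-surface standoff
    bump_height: float = 6.0        # mm
    bump_sigma: float = 8.0         # mm
    depth_noise_sd: float = 0.2     # mm, per-pixel sensor noise
    occlude_top_px: int = 0         # rows occluded by a mandible-like plane
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("neck_radius", "neck_distance", "bump_height", "bump_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depth_noise_sd < 0:
            raise ValueError("depth_noise_sd must be >= 0")
        if self.occlude_top_px < 0:
            raise ValueError("occlude_top_px must be >= 0")
        if self.bump_height >= self.neck_distance:
            raise ValueError("bump_height must be < neck_distance")


def default_meta(subject_id: str = "synthetic") -> SequenceMeta:
    """Default synthetic camera: 256x256 px, 30 fps, fx=fy=300, 400 mm standoff."""
    return SequenceMeta(fps=30.0, width=256, height=256,
                        intrinsics=CameraIntrinsics(300.0, 300.0, 127.5, 127.5),
                        subject_id=subject_id, depth_unit_scale=0.1)


def reduced_meta(subject_id: str = "synthetic") -> SequenceMeta:
    """Desk-scale camera: 128x128 px with tight framing (fx=fy=600).

    A quarter-area sensor framed tightly on the prominence keeps the
    millimetre-per-pixel pitch (0.67 mm at 400 mm standoff) fine enough to
    resolve the small lateral excursion while the full cranio-caudal travel
    stays inside the frame.
    """
    return SequenceMeta(fps=30.0, width=128, height=128,
                        intrinsics=CameraIntrinsics(600.0, 600.0, 63.5, 63.5),
                        subject_id=subject_id, depth_unit_scale=0.1)


def _raised_cosine(phase: np.ndarray) -> np.ndarray:
    """C1 pulse on [0, 1]: 0 at the ends, 1 at phase 0.5."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(phase, 0.0, 1.0)))


def generate_trajectory(params: TrajectoryParams, fps: float, duration: float,
                        rest: tuple[float, float, float] = (0.0, 0.0, 0.0)
                        ) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Simulate the prominence trajectory in camera-frame coordinates.

    Swallow i occupies [i*(rest+swallow) + rest, ... + swallow]; each pulse
    moves the prominence cranially (image up, -Y) by ``amp_cc``, anteriorly
    (toward the camera, -Z) by ``amp_ap``, and laterally by a +/- amp_lr/2
    wobble (one half-cycle each way), then returns to rest.  Per-frame
    Gaussian jitter (``jitter_sd``) is added on all three axes.

    Returns ``(times, points, events)`` with ``points`` of shape (N, 3) in
    camera-frame mm about ``rest`` and ``events`` a list of dicts with the
    start/peak/end frame index of each swallow.
    """
    if fps <= 0 or duration <= 0:
        raise ValueError("fps and duration must be > 0")
    if duration < params.min_duration:
        raise ValueError(
            f"duration {duration} s too short for {params.n_swallows} swallows; "
            f"minimum is {params.min_duration} s")
    n = int(round(duration * fps))
    times = np.arange(n) / fps
    disp = np.zeros((n, 3))
    events: list[dict] = []
    cycle = params.rest_duration + params.swallow_duration
    for i in range(params.n_swallows):
        t0 = i * cycle + params.rest_duration
        phase = (times - t0) / params.swallow_duration
        active = (phase >= 0.0) & (phase <= 1.0)
        ph = phase[active]
        pulse = _raised_cosine(ph)
        # lateral wobble: half-amplitude excursion right then left
        wob = np.where(ph < 0.5, _raised_cosine(2 * ph), -_raised_cosine(2 * ph - 1))
        disp[active, 0] += 0.5 * params.amp_lr * wob
        disp[active, 1] += -params.amp_cc * pulse   # cranial = image up = -Y
        disp[active, 2] += -params.amp_ap * pulse   # anterior = toward camera = -Z
        if active.any():
            idx = np.nonzero(active)[0]
            events.append({"start": int(idx[0]),
                           "peak": int(idx[np.argmax(pulse)]),
                           "end": int(idx[-1])})
    if params.jitter_sd > 0:
        rng = np.random.default_rng(params.seed)
        disp += rng.normal(0.0, params.jitter_sd, size=disp.shape)
    points = disp + np.asarray(rest, dtype=float)
    return times, points, events


def _background_depth(world_x: np.ndarray, scene: SceneParams) -> np.ndarray:
    """Depth of the neck cylinder at lateral world offset ``world_x`` (mm)."""
    r = scene.neck_radius
    x = np.clip(world_x, -0.95 * r, 0.95 * r)
    return scene.neck_distance + r - np.sqrt(r * r - x * x)


def scene_depth(pixel_x: np.ndarray, pixel_y: np.ndarray,
                prominence: np.ndarray, scene: SceneParams,
                intrinsics: CameraIntrinsics) -> np.ndarray:
    """Analytic noise-free scene depth at the given pixels.

    ``prominence`` is the (X, Y, Z) camera-frame position of the bump apex.
    The surface is the cylindrical background minus a Gaussian bump whose
    height is set so that the depth at the apex equals the prominence Z.
    """
    px, py = np.asarray(pixel_x, dtype=float), np.asarray(pixel_y, dtype=float)
    # world coordinates of each pixel ray evaluated at the background surface
    zb0 = np.full(px.shape, scene.neck_distance)
    for _ in range(3):   # fixed-point: depth depends on lateral world coord
        wx = (px - intrinsics.cx) * zb0 / intrinsics.fx
        zb0 = _background_depth(wx, scene)
    wx = (px - intrinsics.cx) * zb0 / intrinsics.fx
    wy = (py - intrinsics.cy) * zb0 / intrinsics.fy
    xp, yp, zp = prominence
    zb_at_p = _background_depth(np.asarray(xp), scene)
    h = zb_at_p - zp
    g = np.exp(-((wx - xp) ** 2 + (wy - yp) ** 2) / (2.0 * scene.bump_sigma ** 2))
    return zb0 - h * g


def render_sequence(times: np.ndarray, points: np.ndarray, scene: SceneParams,
                    meta: SequenceMeta) -> tuple[list[RGBDFrame], list[PointLabel]]:
    """Render an RGBD sequence from a prominence trajectory.

    Per frame: depth = analytic scene depth plus seeded Gaussian sensor
    noise (clipped at 0); color = lambertian-style shading of the depth
    gradient so the bump is visible in RGB; label = forward projection of
    the prominence.  Frames whose prominence projects outside the image are
    rendered but get no label (a warning is logged).
    """
    points = np.asarray(points, dtype=float)
    if len(times) != len(points):
        raise ValueError("times and points must have equal length")
    h, w = meta.height, meta.width
    px, py = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    rng = np.random.default_rng(scene.seed)
    frames: list[RGBDFrame] = []
    labels: list[PointLabel] = []
    pixels = project_array(points, meta.intrinsics)
    for i, (t, point) in enumerate(zip(times, points)):
        depth = scene_depth(px, py, point, scene, meta.intrinsics)
        if scene.occlude_top_px > 0:
            # mandible stand-in: a near plane hiding the top image band
            depth[:scene.occlude_top_px, :] = scene.neck_distance - 80.0
        if scene.depth_noise_sd > 0:
            depth = depth + rng.normal(0.0, scene.depth_noise_sd, size=depth.shape)
        depth = np.clip(depth, 0.0, None).astype(np.float32)
        gx = np.gradient(depth, axis=1)
        gy = np.gradient(depth, axis=0)
        shade = np.clip(150.0 - 120.0 * gx - 60.0 * gy, 0, 255)
        color = np.stack([shade, np.clip(shade * 0.85 + 15, 0, 255),
                          np.clip(shade * 0.7 + 25, 0, 255)], axis=-1).astype(np.uint8)
        frames.append(RGBDFrame(color=color, depth=depth, index=i,
                                timestamp=float(t)))
        lx, ly = pixels[i]
        if 0 <= lx < w and 0 <= ly < h:
            labels.append(PointLabel(i, float(lx), float(ly)))
        else:
            logger.warning("frame %d: prominence projects outside image "
                           "(%.1f, %.1f); label omitted", i, lx, ly)
    return frames, labels


@dataclass(frozen=True)
class DatasetConfig:
    """Configuration of a multi-subject synthetic dataset.

    ``draw_amplitudes`` samples per-subject amplitudes from the cohort
    mean +/- SD (truncated at 0); otherwise every subject uses the base
    amplitudes.  ``n_train`` of the ``n_subjects`` sequences are assigned
    to the training split, the rest to validation.
    """

    n_subjects: int = 7
    n_train: int = 5
    duration: float = 15.0          # s per recording
    seed: int = 0
    draw_amplitudes: bool = True
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    scene: SceneParams = field(default_factory=SceneParams)
    reduced: bool = False           # use the 128 px tight-framing camera

    def __post_init__(self) -> None:
        if not (1 <= self.n_train < self.n_subjects):
            raise ValueError("need 1 <= n_train < n_subjects")


def reduced_dataset_config(seed: int = 0) -> DatasetConfig:
    """Desk-scale dataset: 5 train / 2 validation sequences of ~300 frames
    at 128x128, three swallows each, cohort-mean amplitudes."""
    return DatasetConfig(
        n_subjects=7, n_train=5, duration=10.0, seed=seed,
        draw_amplitudes=True,
        trajectory=TrajectoryParams(rest_duration=1.2, seed=seed),
        scene=SceneParams(bump_sigma=6.0, seed=seed),
        reduced=True)


def draw_subject_amplitudes(rng: np.random.Generator) -> dict[str, float]:
    """Draw per-subject amplitudes from the cohort mean +/- SD, truncated at 0."""
    return {ax: max(0.0, float(rng.normal(AMPLITUDE_MEAN[ax], AMPLITUDE_SD[ax])))
            for ax in ("lr", "cc", "ap")}


def load_trajectory_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ground-truth trajectory CSV (t, X, Y, Z) -> (times, points)."""
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return rows[:, 0], rows[:, 1:4]


def make_dataset(config: DatasetConfig, out_dir: str | Path) -> dict:
    """Generate and write a full synthetic dataset; returns the manifest.

    Each subject directory holds the RGBD sequence, its ``labels.csv`` and
    the ground-truth world ``trajectory.csv``; ``manifest.yaml`` records
    the split membership, seeds and per-subject parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    subjects = []
    for s in range(config.n_subjects):
        sid = f"subj{s:02d}"
        seq_dir = out_dir / sid
        # independent, recorded sub-seeds for amplitudes / jitter / sensor noise
        amp_seed, traj_seed, scene_seed = (
            int(x.generate_state(1)[0] % (2 ** 31)) for x in subject_seeds[s].spawn(3))
        if config.draw_amplitudes:
            amps = draw_subject_amplitudes(np.random.default_rng(amp_seed))
        else:
            amps = {"lr": config.trajectory.amp_lr,
                    "cc": config.trajectory.amp_cc,
                    "ap": config.trajectory.amp_ap}
        tp = replace(config.trajectory, amp_lr=amps["lr"], amp_cc=amps["cc"],
                     amp_ap=amps["ap"], seed=traj_seed)
        sp = replace(config.scene, seed=scene_seed)
        meta = (reduced_meta(sid) if config.reduced else default_meta(sid))
        rest = (0.0, 0.0, sp.neck_distance - sp.bump_height)
        times, points, events = generate_trajectory(tp, meta.fps, config.duration,
                                                    rest=rest)
        frames, labels = render_sequence(times, points, sp, meta)
        write_sequence(frames, meta, seq_dir)
        write_labels(labels, seq_dir / "labels.csv")
        with open(seq_dir / "trajectory.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "X", "Y", "Z"])
            for t, p in zip(times, points):
                writer.writerow([repr(float(t))] + [repr(float(v)) for v in p])
        subjects.append({
            "subject_id": sid,
            "path": sid,
            "split": "train" if s < config.n_train else "validation",
            "n_frames": len(frames),
            "n_labels": len(labels),
            "amplitudes_mm": {k: float(v) for k, v in amps.items()},
            "seeds": {"amplitudes": amp_seed, "trajectory": traj_seed,
                      "scene": scene_seed},
            "events": events,
        })
    manifest = {
        "master_seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_train": config.n_train,
        "duration_s": config.duration,
        "reduced": config.reduced,
        "trajectory_defaults": asdict(config.trajectory),
        "scene_defaults": asdict(config.scene),
        "subjects": subjects,
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
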