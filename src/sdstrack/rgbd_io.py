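"""On-disk dialect for RGBD sequences, camera metadata and point labels.

A sequence is a directory of paired still images plus one YAML sidecar:

    000000_color.png   8-bit RGB
    000000_depth.png   16-bit single-channel, integer depth units
    000001_color.png
    000001_depth.png
    ...
    sequence.yaml      fps, width, height, fx, fy, cx, cy,
                       depth_unit_scale, subject_id, timestamps

Depth is stored as unsigned 16-bit integers with an explicit millimetre-per-
unit scale (``depth_unit_scale``, default 1.0), matching commodity depth-
camera conventions; a stored value of 0 means "no return".  In memory depth
is always float millimetres.

Point labels (one per annotated frame) travel as a flat CSV with header
``frame_index,x,y``; pixel coordinates are 0-based, x rightward, y downward,
and may be sub-pixel.  A convenience importer for CVAT points-XML is
provided for annotations made with that tool.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import yaml

from .geometry import CameraIntrinsics

__all__ = [
    "RGBDFrame", "SequenceMeta", "PointLabel",
    "write_sequence", "read_sequence",
    "read_labels", "write_labels", "read_cvat_points_xml",
]

_STEM_WIDTH = 6


@dataclass
class RGBDFrame:
    """One time point: color raster + depth raster (millimetres)."""

    color: np.ndarray      # (H, W, 3) uint8
    depth: np.ndarray      # (H, W) float32, mm; 0 = invalid / no return
    index: int
    timestamp: float       # seconds from sequence start

    def __post_init__(self) -> None:
        self.color = np.asarray(self.color)
        self.depth = np.asarray(self.depth)
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise ValueError("color must be (H, W, 3)")
        if self.depth.shape != self.color.shape[:2]:
            raise ValueError("color and depth must share height and width")
        if self.color.dtype != np.uint8:
            raise ValueError("color must be uint8")
        if (self.depth < 0).any():
            raise ValueError("depth values must be >= 0 mm")
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    @property
    def height(self) -> int:
        return self.color.shape[0]

    @property
    def width(self) -> int:
        return self.color.shape[1]


@dataclass
class SequenceMeta:
    """Sequence-level metadata; written verbatim into the sidecar."""

    fps: float
    width: int
    height: int
    intrinsics: CameraIntrinsics
    subject_id: str = ""
    depth_unit_scale: float = 1.0   # mm per stored depth integer

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be >= 1")
        if self.depth_unit_scale <= 0:
            raise ValueError("depth_unit_scale must be > 0")


@dataclass
class PointLabel:
    """Pixel annotation of the laryngeal prominence in one frame."""

    frame_index: int
    x: float
    y: float


def _stem(index: int) -> str:
    return f"{index:0{_STEM_WIDTH}d}"


def write_sequence(frames: list[RGBDFrame], meta: SequenceMeta,
                   destination: str | Path) -> Path:
    """Write an RGBD sequence to ``destination`` in the package dialect.

    Depth is quantised to the nearest multiple of ``meta.depth_unit_scale``;
    color is stored losslessly.  Returns the destination path.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    max_stored = 65535 * meta.depth_unit_scale
    for frame in frames:
        if frame.height != meta.height or frame.width != meta.width:
            raise ValueError(
                f"frame {frame.index}: dimensions {frame.height}x{frame.width} "
                f"do not match sequence meta {meta.height}x{meta.width}")
        if (frame.depth > max_stored).any():
            raise ValueError(
                f"frame {frame.index}: depth exceeds 16-bit range at "
                f"scale {meta.depth_unit_scale}")
        stem = _stem(frame.index)
        imageio.imwrite(destination / f"{stem}_color.png", frame.color)
        stored = np.round(frame.depth / meta.depth_unit_scale).astype(np.uint16)
        imageio.imwrite(destination / f"{stem}_depth.png", stored)
    sidecar = {
        "fps": float(meta.fps),
        "width": int(meta.width),
        "height": int(meta.height),
        "fx": float(meta.intrinsics.fx),
        "fy": float(meta.intrinsics.fy),
        "cx": float(meta.intrinsics.cx),
        "cy": float(meta.intrinsics.cy),
        "depth_unit_scale": float(meta.depth_unit_scale),
        "subject_id": str(meta.subject_id),
        "timestamps": {int(f.index): float(f.timestamp) for f in frames},
    }
    with open(destination / "sequence.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return destination


def read_sequence(source: str | Path) -> tuple[list[RGBDFrame], SequenceMeta]:
    """Read a sequence directory written by :func:`write_sequence`.

    Frames are returned sorted by numeric stem regardless of filesystem
    listing order; stored depth integers are converted to millimetres.
    """
    source = Path(source)
    sidecar_path = source / "sequence.yaml"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sc = yaml.safe_load(fh)
    meta = SequenceMeta(
        fps=sc["fps"], width=sc["width"], height=sc["height"],
        intrinsics=CameraIntrinsics(sc["fx"], sc["fy"], sc["cx"], sc["cy"]),
        subject_id=sc.get("subject_id", ""),
        depth_unit_scale=sc.get("depth_unit_scale", 1.0),
    )
    timestamps = sc.get("timestamps", {})

    color_files = sorted(source.glob("*_color.png"))
    if not color_files:
        raise FileNotFoundError(f"no frames found in {source}")
    seen: dict[int, Path] = {}
    frames: list[RGBDFrame] = []
    for cpath in color_files:
        stem = cpath.name[:-len("_color.png")]
        index = int(stem)
        if index in seen:
            raise ValueError(f"stem collision: {cpath.name} vs {seen[index].name}")
        seen[index] = cpath
        dpath = source / f"{stem}_depth.png"
        if not dpath.exists():
            raise FileNotFoundError(f"missing depth partner for {cpath.name}")
        color = np.asarray(imageio.imread(cpath), dtype=np.uint8)
        stored = np.asarray(imageio.imread(dpath))
        depth = stored.astype(np.float32) * meta.depth_unit_scale
        ts = float(timestamps.get(index, index / meta.fps))
        frames.append(RGBDFrame(color=color, depth=depth, index=index, timestamp=ts))
    frames.sort(key=lambda f: f.index)
    return frames, meta


def write_labels(labels: list[PointLabel], destination: str | Path) -> Path:
    """Write point labels as CSV with header ``frame_index,x,y``."""
    destination = Path(destination)
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "x", "y"])
        for lab in labels:
            writer.writerow([lab.frame_index, repr(float(lab.x)), repr(float(lab.y))])
    return destination


def read_labels(source: str | Path,
                image_size: tuple[int, int] | None = None) -> list[PointLabel]:
    """Read a label CSV; rows come back in file order.

    Parameters
    ----------
    image_size : optional (width, height); when given, labels outside
        ``0 <= x < width`` / ``0 <= y < height`` raise a ValueError.
    """
    source = Path(source)
    labels: list[PointLabel] = []
    with open(source, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["frame_index", "x", "y"]:
            raise ValueError(f"{source}: expected header 'frame_index,x,y'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                idx, x, y = int(row[0]), float(row[1]), float(row[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{source}: malformed row at line {lineno}: {row!r}") from exc
            if image_size is not None:
                w, h = image_size
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(
                        f"{source}: label at line {lineno} outside image "
                        f"bounds {w}x{h}: ({x}, {y})")
            labels.append(PointLabel(idx, x, y))
    return labels


def read_cvat_points_xml(source: str | Path) -> list[PointLabel]:
    """Import single-point annotations from CVAT 'annotations.xml' (points mode).

    Reads every ``<points>`` element (inside ``<image>`` or ``<track>``
    containers) and takes the first coordinate pair of its ``points``
    attribute as the label for that frame.
    """
    tree = ET.parse(Path(source))
    labels: list[PointLabel] = []
    for image in tree.getroot().iter("image"):
        frame = int(image.get("id", image.get("frame", "0")))
        for pts in image.iter("points"):
            first = pts.get("points", "").split(";")[0]
            x, y = (float(v) for v in first.split(","))
            labels.append(PointLabel(frame, x, y))
    for track in tree.getroot().iter("track"):
        for pts in track.iter("points"):
            frame = int(pts.get("frame", "0"))
            first = pts.get("points", "").split(";")[0]
            x, y = (float(v) for v in first.split(","))
            labels.append(PointLabel(frame, x, y))
    labels.sort(key=lambda l: l.frame_index)
    return labels
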