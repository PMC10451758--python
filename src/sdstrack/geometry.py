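"""Pinhole camera geometry: pixel+depth <-> metric camera coordinates.

The depth camera reports, for each pixel (x, y), the distance D (mm) along
the optical axis to the surface seen at that pixel.  With known intrinsics
(focal lengths fx, fy in pixels and principal point cx, cy) the metric
position of that surface point in the camera frame is

    X = (x - cx) * D / fx
    Y = (y - cy) * D / fy
    Z = D

Axes follow the pixel conventions: X rightward, Y downward, Z along the
optical axis away from the camera.  Anatomical axis mapping (left-right,
cranio-caudal, anterior-posterior) is deliberately *not* done here; see
:mod:`sdstrack.metrics`.

Lens distortion is assumed negligible or already corrected upstream; feed
undistorted pixel coordinates if your camera has significant distortion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CameraIntrinsics", "WorldPoint", "backproject", "project",
           "backproject_array", "project_array"]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths (pixels) and principal point (pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fx) and self.fx > 0):
            raise ValueError(f"fx must be finite and > 0, got {self.fx}")
        if not (np.isfinite(self.fy) and self.fy > 0):
            raise ValueError(f"fy must be finite and > 0, got {self.fy}")
        if not (np.isfinite(self.cx) and np.isfinite(self.cy)):
            raise ValueError("principal point must be finite")


@dataclass(frozen=True)
class WorldPoint:
    """A point in the camera frame, millimetres.  Z is optical-axis depth."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def backproject(pixel: tuple[float, float], depth: float,
                intrinsics: CameraIntrinsics) -> WorldPoint:
    """Map a pixel coordinate plus its depth reading to camera-frame mm.

    A depth of 0 mm means "no return" on commodity depth sensors; the result
    is then the degenerate point (0, 0, 0), which callers must treat as
    invalid.
    """
    x, y = pixel
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(depth)):
        raise ValueError("pixel coordinates and depth must be finite")
    if depth < 0:
        raise ValueError(f"depth must be >= 0 mm, got {depth}")
    X = (x - intrinsics.cx) * depth / intrinsics.fx
    Y = (y - intrinsics.cy) * depth / intrinsics.fy
    return WorldPoint(X, Y, float(depth))


def project(point: WorldPoint | tuple[float, float, float],
            intrinsics: CameraIntrinsics) -> tuple[float, float]:
    """Map a camera-frame point (mm) to its pixel coordinate.

    Inverse of :func:`backproject` for Z > 0.
    """
    if isinstance(point, WorldPoint):
        X, Y, Z = point.x, point.y, point.z
    else:
        X, Y, Z = point
    if not all(np.isfinite(v) for v in (X, Y, Z)):
        raise ValueError("point coordinates must be finite")
    if Z <= 0:
        raise ValueError("point behind or on camera plane (Z <= 0)")
    x = X * intrinsics.fx / Z + intrinsics.cx
    y = Y * intrinsics.fy / Z + intrinsics.cy
    return (x, y)


def backproject_array(pixels: np.ndarray, depths: np.ndarray,
                      intrinsics: CameraIntrinsics) -> np.ndarray:
    """Vectorised :func:`backproject`.

    Parameters
    ----------
    pixels : (N, 2) array of (x, y) pixel coordinates.
    depths : (N,) array of depths, mm; zeros give the degenerate origin point.

    Returns
    -------
    (N, 3) array of camera-frame coordinates in mm.
    """
    pixels = np.asarray(pixels, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 2:
        raise ValueError("pixels must have shape (N, 2)")
    if depths.shape != (pixels.shape[0],):
        raise ValueError("depths must have shape (N,)")
    if not (np.isfinite(pixels).all() and np.isfinite(depths).all()):
        raise ValueError("pixel coordinates and depths must be finite")
    if (depths < 0).any():
        raise ValueError("depths must be >= 0 mm")
    out = np.empty((pixels.shape[0], 3), dtype=float)
    out[:, 0] = (pixels[:, 0] - intrinsics.cx) * depths / intrinsics.fx
    out[:, 1] = (pixels[:, 1] - intrinsics.cy) * depths / intrinsics.fy
    out[:, 2] = depths
    return out


def project_array(points: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Vectorised :func:`project`.  points: (N, 3) mm, all Z > 0 -> (N, 2) pixels."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (N, 3)")
    if (points[:, 2] <= 0).any():
        raise ValueError("point behind or on camera plane (Z <= 0)")
    out = np.empty((points.shape[0], 2), dtype=float)
    out[:, 0] = points[:, 0] * intrinsics.fx / points[:, 2] + intrinsics.cx
    out[:, 1] = points[:, 1] * intrinsics.fy / points[:, 2] + intrinsics.cy
    return out
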