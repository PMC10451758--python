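"""ROI-based section normalization and fused RGBD model-input assembly.

Rather than normalising whole frames, statistics (mean, SD) are computed
over a region of interest around the laryngeal prominence, each channel is
clipped to mean +/- k*SD and affinely rescaled to [0, 1].  This emphasises
local contrast: the prominence stands out as a blob in the normalised depth
channel.  The normalised ROI is resized to the square network input size
and stacked as R, G, B, depth -> an (S, S, 4) tensor, and the crop+resize
transform is recorded so model outputs (normalised crop coordinates) can be
mapped back to full-frame pixels.

One fixed ROI is used for a whole sequence: the normalisation window never
follows the tracked point, so per-frame statistics stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rgbd_io import RGBDFrame, SequenceMeta

__all__ = ["ROI", "NormalizationParams", "CropTransform",
           "normalize_roi", "fuse_rgbd", "default_roi",
           "resize_bilinear", "blob_preview"]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned region of interest; ``x0, y0`` top-left, inclusive, 0-based."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be >= 0")

    def check_inside(self, frame_height: int, frame_width: int) -> None:
        if self.x0 + self.width > frame_width or self.y0 + self.height > frame_height:
            raise ValueError(
                f"ROI {self} extends outside {frame_height}x{frame_width} frame")

    def contains(self, x: float, y: float) -> bool:
        return (self.x0 <= x < self.x0 + self.width
                and self.y0 <= y < self.y0 + self.height)


@dataclass(frozen=True)
class NormalizationParams:
    """Section-normalisation settings.

    k_clip : clip bounds are mean +/- k_clip * SD (population SD over valid
        ROI pixels).  2.0 keeps ~95% of a Gaussian channel unsaturated.
    per_channel : normalise R, G, B independently; when False the three
        color channels share joint statistics.  Depth always has its own
        statistics (different units).
    """

    k_clip: float = 2.0
    per_channel: bool = True

    def __post_init__(self) -> None:
        if self.k_clip <= 0:
            raise ValueError("k_clip must be > 0")


@dataclass(frozen=True)
class CropTransform:
    """Affine map between full-frame pixels and normalised crop coordinates.

    Normalised coordinates u, v are in [0, 1] over the (resized) crop;
    resized pixel centres sit at (q + 0.5) / out_size.
    """

    x0: float
    y0: float
    crop_width: float
    crop_height: float
    out_size: int

    def to_normalized(self, x: float, y: float) -> tuple[float, float]:
        """Full-frame pixel -> crop-normalised [0, 1] coordinates."""
        u = (x - self.x0 + 0.5) / self.crop_width
        v = (y - self.y0 + 0.5) / self.crop_height
        return (u, v)

    def to_fullframe(self, u, v):
        """Crop-normalised [0, 1] coordinates -> full-frame pixel (arrays ok)."""
        x = np.asarray(u) * self.crop_width + self.x0 - 0.5
        y = np.asarray(v) * self.crop_height + self.y0 - 0.5
        return (x, y)


def _channel_normalize(values: np.ndarray, valid: np.ndarray, k: float) -> np.ndarray:
    vals = values[valid]
    if vals.size == 0:
        raise ValueError("empty ROI: no valid pixels for normalization")
    mu = float(vals.mean())
    sigma = float(vals.std())      # population SD: descriptive image statistic
    if sigma == 0.0:
        return np.full(values.shape, 0.5, dtype=np.float32)
    lo, hi = mu - k * sigma, mu + k * sigma
    out = np.clip(values.astype(np.float64), lo, hi)
    return ((out - lo) / (hi - lo)).astype(np.float32)


def normalize_roi(frame: RGBDFrame, roi: ROI,
                  params: NormalizationParams = NormalizationParams()) -> np.ndarray:
    """Section-normalise a frame over ``roi`` -> (h, w, 4) float32 in [0, 1].

    Channel order R, G, B, depth.  Zero-depth pixels ("no return") are
    excluded from the depth statistics but still mapped through the clip;
    a ROI with no valid depth pixel raises ``ValueError("empty ROI...")``.
    A zero-variance channel comes back as constant 0.5.
    """
    roi.check_inside(frame.height, frame.width)
    color = frame.color[roi.y0:roi.y0 + roi.height, roi.x0:roi.x0 + roi.width, :]
    depth = frame.depth[roi.y0:roi.y0 + roi.height, roi.x0:roi.x0 + roi.width]
    out = np.empty((roi.height, roi.width, 4), dtype=np.float32)
    all_valid = np.ones(depth.shape, dtype=bool)
    if params.per_channel:
        for c in range(3):
            out[:, :, c] = _channel_normalize(color[:, :, c].astype(np.float64),
                                              all_valid, params.k_clip)
    else:
        joint = color.astype(np.float64)
        vals = joint.reshape(-1)
        mu, sigma = float(vals.mean()), float(vals.std())
        if sigma == 0.0:
            out[:, :, :3] = 0.5
        else:
            lo, hi = mu - params.k_clip * sigma, mu + params.k_clip * sigma
            out[:, :, :3] = ((np.clip(joint, lo, hi) - lo) / (hi - lo)).astype(np.float32)
    valid_depth = depth > 0
    if not valid_depth.any():
        raise ValueError("empty ROI: no valid depth pixels")
    out[:, :, 3] = _channel_normalize(depth.astype(np.float64), valid_depth,
                                      params.k_clip)
    return out


def resize_bilinear(image: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Bilinear resize of an (H, W) or (H, W, C) array.

    Uses the pixel-centre convention: output pixel q samples input
    coordinate (q + 0.5) * in/out - 0.5, with edge clamping.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    ys = (np.arange(out_height) + 0.5) * (h / out_height) - 0.5
    xs = (np.arange(out_width) + 0.5) * (w / out_width) - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)
    wx = np.clip(xs - x0, 0.0, 1.0)
    if image.ndim == 2:
        img = image[:, :, None]
    else:
        img = image
    top = img[y0][:, x0] * (1 - wx)[None, :, None] + img[y0][:, x1] * wx[None, :, None]
    bot = img[y1][:, x0] * (1 - wx)[None, :, None] + img[y1][:, x1] * wx[None, :, None]
    out = top * (1 - wy)[:, None, None] + bot * wy[:, None, None]
    out = out.astype(image.dtype if np.issubdtype(image.dtype, np.floating) else np.float32)
    return out[:, :, 0] if image.ndim == 2 else out


def fuse_rgbd(frame: RGBDFrame, roi: ROI, target_size: int,
              params: NormalizationParams = NormalizationParams()
              ) -> tuple[np.ndarray, CropTransform]:
    """Build the fused 4-channel model input for one frame.

    Returns the (target_size, target_size, 4) float32 tensor (channels
    R, G, B, depth, values in [0, 1]) and the :class:`CropTransform` that
    maps predictions back to full-frame pixel coordinates.
    """
    if target_size < 8:
        raise ValueError(f"target_size must be >= 8, got {target_size}")
    norm = normalize_roi(frame, roi, params)
    if (roi.height, roi.width) != (target_size, target_size):
        norm = resize_bilinear(norm, target_size, target_size)
    transform = CropTransform(x0=float(roi.x0), y0=float(roi.y0),
                              crop_width=float(roi.width),
                              crop_height=float(roi.height),
                              out_size=target_size)
    return norm.astype(np.float32), transform


def default_roi(meta: SequenceMeta, marker: tuple[float, float]) -> ROI:
    """Square ROI centred on the resting-prominence marker.

    Side length is half the frame's smaller dimension; the ROI is shifted
    minimally to stay inside the frame.
    """
    mx, my = marker
    if not (0 <= mx < meta.width and 0 <= my < meta.height):
        raise ValueError(f"marker {marker} outside {meta.width}x{meta.height} frame")
    side = min(meta.width, meta.height) // 2
    x0 = int(round(mx - side / 2))
    y0 = int(round(my - side / 2))
    x0 = min(max(x0, 0), meta.width - side)
    y0 = min(max(y0, 0), meta.height - side)
    return ROI(x0=x0, y0=y0, width=side, height=side)


def blob_preview(frames: list[RGBDFrame], roi: ROI,
                 params: NormalizationParams = NormalizationParams(),
                 quantile: float = 0.02) -> dict:
    """Diagnostic tracker: centroid of the near-surface depth blob per frame.

    After section normalisation the prominence appears as the region of
    smallest normalised depth (closest to the camera).  The centroid of the
    pixels at or below the given depth quantile gives a quick sanity
    trajectory and a preview motion distance without any trained model.
    Returns full-frame pixel centroids (N, 2) and the per-axis pixel ranges.
    """
    centroids = np.full((len(frames), 2), np.nan)
    for i, frame in enumerate(frames):
        norm = normalize_roi(frame, roi, params)
        nd = norm[:, :, 3]
        thresh = np.quantile(nd, quantile)
        mask = nd <= thresh
        if not mask.any():
            continue
        ys, xs = np.nonzero(mask)
        centroids[i] = (roi.x0 + xs.mean(), roi.y0 + ys.mean())
    valid = ~np.isnan(centroids[:, 0])
    ranges = (np.ptp(centroids[valid], axis=0) if valid.sum() >= 2
              else np.array([0.0, 0.0]))
    return {"centroids": centroids,
            "pixel_range_x": float(ranges[0]),
            "pixel_range_y": float(ranges[1])}
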