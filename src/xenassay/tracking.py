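"""Video tracking of a free-swimming tadpole.

Turns a behavioral video (array of grayscale frames) into a calibrated
trajectory: the petri dish is detected to fix the mm scale, a temporal-median
background is subtracted, the animal is segmented by thresholding, the mask
is fit to an ellipse, and the 180-degree orientation ambiguity of the ellipse
is resolved against the motion direction to give an unwrapped heading series.

Conventions: image coordinates, x right, y down; angles in degrees measured
by atan2(dy, dx) so that positive angles rotate from +x toward +y (downward
on screen).  Orientations are reported modulo 180, headings modulo 360 before
unwrapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import feature, measure

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationError",
    "CalibratedScale",
    "EllipsePose",
    "TrackingConfig",
    "Trajectory",
    "detect_dish_scale",
    "estimate_background",
    "segment_tadpole",
    "fit_ellipse_pose",
    "resolve_heading",
    "track_video",
    "load_frames",
]


class CalibrationError(RuntimeError):
    """No circular dish boundary found; supply the scale manually."""


def _circle_params(model) -> Tuple[float, float, float]:
    if hasattr(model, "radius"):
        (cx, cy), r = model.center, model.radius
    else:  # older scikit-image API
        cx, cy, r = model.params
    return float(cx), float(cy), float(r)


def _fit_circle(points: np.ndarray):
    """Least-squares circle fit across scikit-image API generations."""
    if hasattr(measure.CircleModel, "from_estimate"):
        model = measure.CircleModel.from_estimate(points)
        return model if bool(model) else None
    model = measure.CircleModel()
    return model if model.estimate(points) else None


@dataclass(frozen=True)
class CalibratedScale:
    """Pixel-to-mm mapping derived from the known dish diameter (60 mm)."""

    px_per_mm: float
    dish_center_px: Tuple[float, float]
    dish_diameter_px: float
    known_diameter_mm: float = 60.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")


@dataclass(frozen=True)
class EllipsePose:
    """Moments-based ellipse fit of a binary mask."""

    centroid_px: Tuple[float, float]  # (x, y)
    major_px: float
    minor_px: float
    orientation_deg: float  # major-axis angle mod 180, image coords


@dataclass
class TrackingConfig:
    known_diameter_mm: float = 60.0
    manual_px_per_mm: Optional[float] = None
    threshold: Optional[float] = None  # None -> Otsu on |frame - background|
    speed_floor_mms: float = 0.5
    max_gap_frames: int = 3
    background_samples: int = 50
    min_mask_px: int = 5
    dish_margin_px: float = 3.0
    invalid_warn_fraction: float = 0.2


@dataclass
class Trajectory:
    """Calibrated per-frame kinematics.

    ``frames`` columns: frame, time_s, x_mm, y_mm, heading_deg (unwrapped),
    major_mm, minor_mm, valid.  Invalid frames carry NaNs.
    """

    frames: pd.DataFrame = field(repr=False)
    fps: float
    scale: CalibratedScale
    heading_ok: bool = True

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def time_s(self) -> np.ndarray:
        return self.frames["time_s"].to_numpy()

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)


def detect_dish_scale(frame: np.ndarray, known_diameter_mm: float = 60.0,
                      rng_seed: int = 0) -> CalibratedScale:
    """Detect the circular dish boundary and derive px/mm.

    Canny edges are fit with a RANSAC circle model, which tolerates the
    animal's own edges and moderate boundary noise.  Raises
    :class:`CalibrationError` when no plausible circle is found.
    """
    img = np.asarray(frame, dtype=float)
    edges = feature.canny(img / max(img.max(), 1.0), sigma=2.0)
    ys, xs = np.nonzero(edges)
    if xs.size < 20:
        raise CalibrationError("no circular feature found; enter the scale manually")
    pts = np.column_stack([xs, ys]).astype(float)
    model, inliers = measure.ransac(
        pts, measure.CircleModel, min_samples=3, residual_threshold=2.0,
        max_trials=300, rng=rng_seed)
    if model is None or inliers is None or inliers.sum() < 20:
        raise CalibrationError("no circular feature found; enter the scale manually")
    # refine on every edge point near the consensus circle: a dish boundary of
    # finite thickness yields inner and outer edge rings, and fitting both
    # centers the estimate on the physical boundary
    cx, cy, r = _circle_params(model)
    dist = np.abs(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r)
    near = dist < 6.0
    if near.sum() >= 20:
        refined = _fit_circle(pts[near])
        if refined is not None:
            cx, cy, r = _circle_params(refined)
    h, w = img.shape
    min_dim = min(h, w)
    if not (0.1 * min_dim <= 2 * r <= 1.5 * min_dim) or not (0 <= cx < w and 0 <= cy < h):
        raise CalibrationError("detected circle implausible; enter the scale manually")
    return CalibratedScale(px_per_mm=2.0 * r / known_diameter_mm,
                           dish_center_px=(float(cx), float(cy)),
                           dish_diameter_px=float(2.0 * r),
                           known_diameter_mm=known_diameter_mm)


def estimate_background(frames: Sequence[np.ndarray], max_samples: int = 50) -> np.ndarray:
    """Per-pixel temporal median over an evenly spaced frame subsample."""
    n = len(frames)
    if n < 10:
        raise ValueError(f"need >= 10 frames for background estimation, got {n}")
    idx = np.linspace(0, n - 1, min(n, max_samples)).round().astype(int)
    stack = np.stack([np.asarray(frames[i], dtype=float) for i in idx])
    return np.median(stack, axis=0)


def segment_tadpole(frame: np.ndarray, background: np.ndarray,
                    threshold: Optional[float] = None,
                    scale: Optional[CalibratedScale] = None,
                    dish_margin_px: float = 3.0) -> np.ndarray:
    """Threshold |frame - background| and keep the largest 8-connected blob.

    With a calibrated scale, pixels outside the dish interior are ignored.
    An empty mask is returned (not an error) when nothing stands out; the
    caller marks the frame invalid.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    diff = np.abs(frame - background)
    if scale is not None:
        h, w = frame.shape
        cx, cy = scale.dish_center_px
        yy, xx = np.mgrid[0:h, 0:w]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= (scale.dish_diameter_px / 2.0
                                                     - dish_margin_px) ** 2
        diff = np.where(inside, diff, 0.0)
    if threshold is None:
        from skimage.filters import threshold_otsu
        if diff.max() - diff.min() < 1e-9:
            return np.zeros(frame.shape, dtype=bool)
        threshold = threshold_otsu(diff)
    mask = diff > threshold
    if not mask.any():
        return mask
    labels, n_lab = measure.label(mask, connectivity=2, return_num=True)
    if n_lab == 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))  # ties -> smaller label index (argmax rule)
    return labels == best


def fit_ellipse_pose(mask: np.ndarray) -> Optional[EllipsePose]:
    """Moments-based ellipse fit; None when fewer than 5 foreground pixels.

    Axis lengths follow the equal-second-moment ellipse (full axes = 4 sqrt
    of the covariance eigenvalues); the orientation is the major-axis angle
    from +x, y down, modulo 180.
    """
    ys, xs = np.nonzero(mask)
    if xs.size < 5:
        return None
    x = xs.astype(float)
    y = ys.astype(float)
    cx, cy = x.mean(), y.mean()
    mu20 = np.mean((x - cx) ** 2)
    mu02 = np.mean((y - cy) ** 2)
    mu11 = np.mean((x - cx) * (y - cy))
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    common = np.sqrt(max(0.0, (mu20 - mu02) ** 2 + 4 * mu11 ** 2))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    return EllipsePose(centroid_px=(float(cx), float(cy)),
                       major_px=float(4.0 * np.sqrt(max(lam1, 0.0))),
                       minor_px=float(4.0 * np.sqrt(max(lam2, 0.0))),
                       orientation_deg=float(np.degrees(theta) % 180.0))


def _ang_diff(a: float, b: float) -> float:
    """Signed smallest difference a - b in (-180, 180]."""
    d = (a - b + 180.0) % 360.0 - 180.0
    return d if d != -180.0 else 180.0


def resolve_heading(orientations_deg: Sequence[float],
                    centroids_px: Sequence[Tuple[float, float]],
                    fps: float,
                    px_per_mm: float,
                    speed_floor_mms: float = 0.5) -> Tuple[np.ndarray, bool]:
    """Resolve the 180-degree orientation ambiguity against motion.

    Where the frame-to-frame speed exceeds ``speed_floor_mms`` the heading is
    the orientation candidate (o or o+180) within 90 degrees of the
    instantaneous displacement direction; below the floor the candidate
    closest to the previous heading is kept.  The result is cumulative
    (unwrapped).  Returns ``(headings, ok)`` with ``ok`` False when no frame
    ever exceeds the floor (headings then resolved against the raw
    orientations, flagged indeterminate).
    """
    ori = np.asarray(orientations_deg, dtype=float)
    cen = np.asarray(centroids_px, dtype=float)
    if ori.shape[0] != cen.shape[0]:
        raise ValueError("orientation and centroid series must have equal length")
    n = ori.shape[0]
    floor_px = speed_floor_mms * px_per_mm / fps  # displacement per frame
    disp = np.full((n, 2), np.nan)
    disp[1:] = cen[1:] - cen[:-1]
    # exponentially smoothed velocity: single-frame displacements carry
    # sub-pixel centroid jitter that would flip the half-plane spuriously
    alpha = 0.4
    vel = np.full((n, 2), np.nan)
    prev_v = None
    for i in range(1, n):
        d = disp[i]
        if not np.all(np.isfinite(d)):
            continue
        prev_v = d if prev_v is None else (1 - alpha) * prev_v + alpha * d
        vel[i] = prev_v
    move_ang = np.degrees(np.arctan2(vel[:, 1], vel[:, 0]))
    moving = np.hypot(vel[:, 0], vel[:, 1]) > floor_px

    valid = np.isfinite(ori)
    headings = np.full(n, np.nan)
    # anchor on the first moving, valid frame
    anchor = next((i for i in range(n) if moving[i] and valid[i]), None)
    ok = anchor is not None
    if anchor is None:
        anchor = next((i for i in range(n) if valid[i]), None)
        if anchor is None:
            return headings, False
        current = ori[anchor]
    else:
        current = ori[anchor]
        if abs(_ang_diff(current, move_ang[anchor])) > 90.0:
            current += 180.0
    headings[anchor] = current

    def _step(i: int, prev: float) -> float:
        cand = ori[i] % 360.0
        if moving[i] and np.isfinite(move_ang[i]):
            ref = move_ang[i]
        else:
            ref = prev
        if abs(_ang_diff(cand, ref)) > 90.0:
            cand += 180.0
        return prev + _ang_diff(cand, prev)

    prev = current
    for i in range(anchor + 1, n):
        if not valid[i]:
            continue
        prev = _step(i, prev)
        headings[i] = prev
    # resolve frames before the anchor by walking backward from it
    prev = current
    for i in range(anchor - 1, -1, -1):
        if not valid[i]:
            continue
        cand = ori[i] % 360.0
        if abs(_ang_diff(cand, prev)) > 90.0:
            cand += 180.0
        prev = prev + _ang_diff(cand, prev)
        headings[i] = prev
    return headings, ok


def _interpolate_gaps(values: np.ndarray, valid: np.ndarray, max_gap: int) -> Tuple[np.ndarray, np.ndarray]:
    """Linearly fill invalid runs of length <= max_gap bounded by valid frames."""
    out = values.copy()
    filled = valid.copy()
    n = len(values)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        if i > 0 and j < n and (j - i) <= max_gap:
            left, right = values[i - 1], values[j]
            for k in range(i, j):
                w = (k - (i - 1)) / (j - (i - 1))
                out[k] = left + w * (right - left)
                filled[k] = True
        i = j
    return out, filled


def track_video(frames: Sequence[np.ndarray], fps: float,
                config: Optional[TrackingConfig] = None) -> Trajectory:
    """Full tracking pipeline: calibrate, subtract background, segment, fit.

    Invalid frames (empty or tiny mask) are linearly interpolated when the
    gap is at most ``config.max_gap_frames``; longer gaps stay invalid.  A
    warning is logged when more than 20% of frames are invalid.
    """
    cfg = config or TrackingConfig()
    if cfg.manual_px_per_mm is not None:
        h, w = np.asarray(frames[0]).shape
        scale = CalibratedScale(px_per_mm=cfg.manual_px_per_mm,
                                dish_center_px=((w - 1) / 2, (h - 1) / 2),
                                dish_diameter_px=cfg.manual_px_per_mm * cfg.known_diameter_mm,
                                known_diameter_mm=cfg.known_diameter_mm)
    else:
        scale = detect_dish_scale(frames[0], cfg.known_diameter_mm)
    background = estimate_background(frames, cfg.background_samples)

    n = len(frames)
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    ori = np.full(n, np.nan)
    major = np.full(n, np.nan)
    minor = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = segment_tadpole(frames[i], background, cfg.threshold, scale,
                               cfg.dish_margin_px)
        if mask.sum() < cfg.min_mask_px:
            continue
        pose = fit_ellipse_pose(mask)
        if pose is None:
            continue
        cx[i], cy[i] = pose.centroid_px
        ori[i] = pose.orientation_deg
        major[i], minor[i] = pose.major_px, pose.minor_px
        valid[i] = True

    invalid_frac = 1.0 - valid.mean() if n else 1.0
    if invalid_frac > cfg.invalid_warn_fraction:
        log.warning("%.0f%% of %d frames could not be tracked", 100 * invalid_frac, n)

    cx, filled = _interpolate_gaps(cx, valid, cfg.max_gap_frames)
    cy, _ = _interpolate_gaps(cy, valid, cfg.max_gap_frames)
    major, _ = _interpolate_gaps(major, valid, cfg.max_gap_frames)
    minor, _ = _interpolate_gaps(minor, valid, cfg.max_gap_frames)
    # orientation in interpolated gaps: carry the nearest previous valid value
    for i in range(n):
        if filled[i] and not valid[i] and i > 0 and np.isfinite(ori[i - 1]):
            ori[i] = ori[i - 1]

    headings, ok = resolve_heading(ori, np.column_stack([cx, cy]), fps,
                                   scale.px_per_mm, cfg.speed_floor_mms)
    t = np.arange(n) / fps
    df = pd.DataFrame({
        "frame": np.arange(n),
        "time_s": t,
        "x_mm": cx / scale.px_per_mm,
        "y_mm": cy / scale.px_per_mm,
        "heading_deg": headings,
        "major_mm": major / scale.px_per_mm,
        "minor_mm": minor / scale.px_per_mm,
        "valid": filled,
    })
    return Trajectory(frames=df, fps=fps, scale=scale, heading_ok=ok)


def load_frames(path, fps: Optional[float] = None) -> Tuple[list, float]:
    """Load a video as grayscale frames from a container file or a frame directory.

    Directories must contain numbered PNG/TIFF frames and require ``fps``;
    container files are opened through imageio and may carry their own fps.
    """
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        if fps is None:
            raise ValueError("fps is required for frame-directory input")
        files = sorted(q for q in p.iterdir()
                       if q.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no PNG/TIFF frames in {p}")
        frames = [_to_gray(iio.imread(f)) for f in files]
        return frames, fps
    arr = iio.imread(p)
    if fps is None:
        meta = iio.immeta(p)
        fps = meta.get("fps")
        if fps is None:
            raise ValueError("container has no fps metadata; pass fps explicitly")
    frames = [_to_gray(f) for f in arr]
    return frames, float(fps)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return img[..., :3].mean(axis=-1)
    return np.asarray(img)
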