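"""Per-trial escape kinematics and response scoring.

Given a tracked trajectory and a loom-onset log, computes the speed series,
pre/post-onset distances (3 s windows, trapezoidal area under the speed
curve), escape distance and peak speed over the 2 s after onset, the escape
angle over a polarity-specific window (0.6 s for dark looms, 1.2 s for
bright looms, matching the observed response latencies), a transparent
threshold-based positive/negative/undeterminable label, and the response
rate (positives over positives + negatives, undeterminable excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import auc_trapezoid
from .tracking import Trajectory

__all__ = [
    "TrialRecord",
    "TrialMetrics",
    "ResponseLabel",
    "ClassifierConfig",
    "ESCAPE_ANGLE_WINDOW_S",
    "speed_series",
    "window_distance",
    "pre_post_distance",
    "escape_metrics",
    "classify_response",
    "response_rate",
    "contrail",
]

#: escape-angle measurement window after loom onset, by stimulus polarity
ESCAPE_ANGLE_WINDOW_S = {"dark": 0.6, "bright": 1.2}


@dataclass(frozen=True)
class TrialRecord:
    trajectory: Trajectory
    onset_s: float
    polarity: str = "dark"
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"polarity must be 'dark' or 'bright', got {self.polarity!r}")


@dataclass(frozen=True)
class ResponseLabel:
    label: str  # positive | negative | undeterminable
    rationale: str


@dataclass
class TrialMetrics:
    trial_id: str
    polarity: str
    pre_distance_mm: float
    post_distance_mm: float
    escape_distance_mm: Optional[float] = None
    max_velocity_mms: Optional[float] = None
    escape_angle_deg: Optional[float] = None
    label: Optional[ResponseLabel] = None


@dataclass
class ClassifierConfig:
    """Threshold rule standing in for the study's blinded human rater.

    A trial is undeterminable when the animal is already moving fast at
    onset; otherwise positive when the post-onset travel clearly exceeds the
    pre-onset travel.  All constants are explicit and configurable; the
    defaults are not claimed to match any particular human rater.
    """

    fast_threshold_mms: float = 5.0   # mean speed over the 0.5 s before onset
    fast_window_s: float = 0.5
    abs_min_mm: float = 5.0           # minimum post-onset travel for a positive
    ratio_min: float = 2.0            # post/pre travel ratio for a positive
    eps_mm: float = 0.5


def speed_series(traj: Trajectory, smooth_window: int = 3) -> pd.DataFrame:
    """Centroid speed in mm/s by central differences (one-sided at the ends).

    Invalid frames propagate as NaN.  ``smooth_window`` applies a centered
    moving average (1 disables smoothing).  Returns columns time_s, speed_mms.
    """
    df = traj.frames
    if int(df["valid"].sum()) < 3:
        raise ValueError("need at least 3 valid frames for a speed series")
    t = df["time_s"].to_numpy()
    x = df["x_mm"].to_numpy().copy()
    y = df["y_mm"].to_numpy().copy()
    x[~df["valid"].to_numpy()] = np.nan
    y[~df["valid"].to_numpy()] = np.nan
    n = len(t)
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    if n >= 2:
        vx[0] = (x[1] - x[0]) / (t[1] - t[0])
        vy[0] = (y[1] - y[0]) / (t[1] - t[0])
        vx[-1] = (x[-1] - x[-2]) / (t[-1] - t[-2])
        vy[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    if n >= 3:
        vx[1:-1] = (x[2:] - x[:-2]) / (t[2:] - t[:-2])
        vy[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    speed = np.hypot(vx, vy)
    if smooth_window > 1:
        k = int(smooth_window)
        kernel = np.ones(k) / k
        pad = k // 2
        padded = np.pad(speed, pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="same")[pad:pad + n]
        # do not let smoothing invent values where the raw speed is missing
        sm[np.isnan(speed)] = np.nan
        speed = sm
    return pd.DataFrame({"time_s": t, "speed_mms": speed})


def _interp_at(t: np.ndarray, y: np.ndarray, t0: float) -> float:
    return float(np.interp(t0, t, y))


def window_distance(speed: pd.DataFrame, t0: float, t1: float) -> float:
    """Trapezoidal integral of the speed series over [t0, t1] (mm)."""
    t = speed["time_s"].to_numpy()
    v = speed["speed_mms"].to_numpy()
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or t1 <= t0:
        raise ValueError(f"window [{t0}, {t1}] not covered by the series "
                         f"[{t[0]}, {t[-1]}]")
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    vv = np.concatenate([[_interp_at(t, v, t0)], v[inside], [_interp_at(t, v, t1)]])
    if np.any(np.isnan(vv)):
        raise ValueError("speed series has missing values inside the window")
    return auc_trapezoid(tt, vv)


def pre_post_distance(trial: TrialRecord, window_s: float = 3.0,
                      smooth_window: int = 3) -> Tuple[float, float]:
    """Distance traveled in the ``window_s`` before and after loom onset."""
    sp = speed_series(trial.trajectory, smooth_window)
    t = sp["time_s"].to_numpy()
    if trial.onset_s - window_s < t[0] - 1e-9 or trial.onset_s + window_s > t[-1] + 1e-9:
        raise ValueError(f"trial {trial.trial_id}: insufficient margin for "
                         f"{window_s} s pre/post windows")
    pre = window_distance(sp, trial.onset_s - window_s, trial.onset_s)
    post = window_distance(sp, trial.onset_s, trial.onset_s + window_s)
    return pre, post


def _heading_at(traj: Trajectory, t0: float) -> float:
    df = traj.frames
    ok = df["valid"].to_numpy() & np.isfinite(df["heading_deg"].to_numpy())
    t = df["time_s"].to_numpy()[ok]
    h = df["heading_deg"].to_numpy()[ok]
    if t.size == 0 or t0 < t[0] - 1e-9 or t0 > t[-1] + 1e-9:
        return np.nan
    # reject if the nearest valid sample is more than one frame interval away
    nearest = np.min(np.abs(t - t0))
    if nearest > 1.5 / traj.fps:
        return np.nan
    return float(np.interp(t0, t, h))


def escape_metrics(trial: TrialRecord, smooth_window: int = 3,
                   angle_window_s: Optional[float] = None) -> TrialMetrics:
    """Escape distance, peak speed (2 s post-onset) and escape angle.

    The escape angle is |heading(onset + w) - heading(onset)| on the
    unwrapped series, with w bound to polarity (0.6 s dark, 1.2 s bright)
    unless overridden; values above 180 are reflected back into [0, 180].
    """
    sp = speed_series(trial.trajectory, smooth_window)
    pre, post = pre_post_distance(trial, smooth_window=smooth_window)
    t0 = trial.onset_s
    esc_dist = window_distance(sp, t0, t0 + 2.0)
    t = sp["time_s"].to_numpy()
    v = sp["speed_mms"].to_numpy()
    in_win = (t >= t0) & (t <= t0 + 2.0)
    vmax = float(np.nanmax(v[in_win])) if in_win.any() else np.nan

    w = angle_window_s if angle_window_s is not None else ESCAPE_ANGLE_WINDOW_S[trial.polarity]
    h0 = _heading_at(trial.trajectory, t0)
    h1 = _heading_at(trial.trajectory, t0 + w)
    if np.isnan(h0) or np.isnan(h1):
        angle = None
    else:
        a = abs(h1 - h0) % 360.0
        angle = 360.0 - a if a > 180.0 else a
    return TrialMetrics(trial_id=trial.trial_id, polarity=trial.polarity,
                        pre_distance_mm=pre, post_distance_mm=post,
                        escape_distance_mm=esc_dist, max_velocity_mms=vmax,
                        escape_angle_deg=angle)


def classify_response(trial: TrialRecord,
                      criteria: Optional[ClassifierConfig] = None,
                      smooth_window: int = 3) -> ResponseLabel:
    """Label a trial positive / negative / undeterminable by threshold rules."""
    cfg = criteria or ClassifierConfig()
    try:
        sp = speed_series(trial.trajectory, smooth_window)
        pre, post = pre_post_distance(trial, smooth_window=smooth_window)
        pre_travel = window_distance(sp, trial.onset_s - cfg.fast_window_s, trial.onset_s)
    except ValueError as exc:
        return ResponseLabel("undeterminable", f"insufficient data: {exc}")
    pre_speed = pre_travel / cfg.fast_window_s
    if pre_speed > cfg.fast_threshold_mms:
        return ResponseLabel(
            "undeterminable",
            f"moving quickly at onset: mean pre-onset speed {pre_speed:.1f} mm/s "
            f"> {cfg.fast_threshold_mms} mm/s")
    needed = max(cfg.abs_min_mm, cfg.ratio_min * max(pre, cfg.eps_mm))
    if post >= needed:
        return ResponseLabel(
            "positive",
            f"post-onset travel {post:.1f} mm >= {needed:.1f} mm "
            f"(pre {pre:.1f} mm)")
    return ResponseLabel(
        "negative",
        f"post-onset travel {post:.1f} mm < {needed:.1f} mm (pre {pre:.1f} mm)")


def response_rate(labels: Sequence[ResponseLabel]) -> float:
    """Positives / (positives + negatives); undeterminable trials excluded."""
    pos = sum(1 for l in labels if l.label == "positive")
    neg = sum(1 for l in labels if l.label == "negative")
    if pos + neg == 0:
        raise ValueError("response rate undefined: no positive or negative trials")
    return pos / (pos + neg)


def contrail(trial: TrialRecord, window_s: float = 2.0) -> np.ndarray:
    """Centroid polyline (mm) over [onset, onset + window_s]; shape (k, 2)."""
    df = trial.trajectory.frames
    t = df["time_s"].to_numpy()
    sel = (t >= trial.onset_s - 1e-9) & (t <= trial.onset_s + window_s + 1e-9) \
        & df["valid"].to_numpy()
    if t[-1] + 1e-9 < trial.onset_s + window_s:
        raise ValueError("trajectory does not cover the contrail window")
    pts = df.loc[sel, ["x_mm", "y_mm"]].to_numpy()
    # collapse consecutive duplicates so a stationary animal gives one point
    if len(pts) > 1:
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
        pts = pts[keep]
    return pts


def draw_contrail_overlay(trial: TrialRecord, frame: np.ndarray,
                          window_s: float = 2.0, value: int = 255) -> np.ndarray:
    """Draw the contrail polyline onto a copy of ``frame`` (px coordinates)."""
    from skimage.draw import line

    pts_mm = contrail(trial, window_s)
    s = trial.trajectory.scale.px_per_mm
    pts = np.round(pts_mm * s).astype(int)
    out = np.asarray(frame).copy()
    h, w = out.shape[:2]
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        out[rr[ok], cc[ok]] = value
    return out
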