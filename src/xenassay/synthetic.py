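"""Synthetic data with recorded ground truth for every assay input.

Generates (a) behavioral videos of a single tadpole in a 60 mm dish with a
pre-stimulus drift and an optional post-stimulus escape burst of known
latency, peak speed and turn angle; (b) two-channel z-stacks in which each
microglial blob's green content is a linear function of the animal's axon
count plus noise over an autofluorescent baseline; (c) day-4/day-5 assay
cohorts with day-dependent slopes and optional contaminated animals;
(d) real-time volume series with a programmed fold-change step; and
(e) channel pairs with a programmed voxel correlation for colocalization
tests.  Every generator is deterministic given its seed and returns its
hidden parameters so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trogo import StackPair, TectumMeasurement

__all__ = [
    "EscapeParams",
    "BehaviorSimParams",
    "StackSimParams",
    "make_behavior_video",
    "make_stack_pair",
    "make_assay_cohort",
    "make_realtime_series",
    "make_coloc_pair",
]


# ---------------------------------------------------------------------------
# behavior video

@dataclass
class EscapeParams:
    """Escape burst: latency from loom onset, exponentially decaying speed."""

    latency_s: float = 0.3
    peak_speed_mms: float = 40.0
    decay_tau_s: float = 0.4
    turn_deg: float = 60.0
    turn_duration_s: float = 0.1


@dataclass
class BehaviorSimParams:
    dish_diameter_mm: float = 60.0
    px_per_mm: float = 4.0
    fps: float = 30.0
    duration_s: float = 8.0
    onset_s: float = 4.0
    pre_speed_mms: float = 2.0
    heading_jitter_deg_s: float = 20.0  # SD of smooth pre-stimulus heading wander
    escape: Optional[EscapeParams] = field(default_factory=EscapeParams)
    tadpole_major_mm: float = 7.0
    tadpole_minor_mm: float = 2.5
    noise_sigma: float = 3.0
    start_radius_mm: float = 6.0  # animal starts within this radius of center
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dish_diameter_mm", "px_per_mm", "fps", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.escape is not None:
            end = self.onset_s + self.escape.latency_s
            if end >= self.duration_s:
                raise ValueError("escape begins after the video ends")


def _simulate_trajectory(p: BehaviorSimParams) -> pd.DataFrame:
    """True centroid/heading/speed series (mm, deg unwrapped, mm/s)."""
    rng = np.random.default_rng(p.seed)
    dt = 1.0 / p.fps
    n = int(round(p.duration_s * p.fps))
    r_wall = p.dish_diameter_mm / 2.0 - p.tadpole_major_mm / 2.0 - 1.0

    ang0 = rng.uniform(0, 360)
    r0 = rng.uniform(0, p.start_radius_mm)
    x = r0 * np.cos(np.radians(ang0))
    y = r0 * np.sin(np.radians(ang0))
    heading = rng.uniform(0, 360)

    t_turn = p.onset_s + p.escape.latency_s if p.escape is not None else np.inf
    turn_frames = max(1, int(round((p.escape.turn_duration_s if p.escape else 0) * p.fps)))
    turn_per_frame = (p.escape.turn_deg / turn_frames) if p.escape else 0.0
    turn_sign = rng.choice([-1.0, 1.0])
    turned = 0

    rows = []
    # smooth wander: AR(1) on the heading increment
    wander = 0.0
    for i in range(n):
        t = i * dt
        if p.escape is not None and t >= t_turn:
            speed = p.pre_speed_mms + (p.escape.peak_speed_mms - p.pre_speed_mms) \
                * np.exp(-(t - t_turn) / p.escape.decay_tau_s)
            if turned < turn_frames:
                heading += turn_sign * turn_per_frame
                turned += 1
        else:
            speed = p.pre_speed_mms
            if p.escape is None or t < p.onset_s:
                # ballistic after onset: the wander pauses so the programmed
                # turn is exactly the ground-truth escape angle
                wander = 0.8 * wander + rng.normal(0, p.heading_jitter_deg_s * dt)
                heading += wander
        rows.append((t, x, y, heading, speed))
        nx = x + speed * dt * np.cos(np.radians(heading))
        ny = y + speed * dt * np.sin(np.radians(heading))
        if np.hypot(nx, ny) > r_wall:
            # reflect heading toward the dish center
            heading = np.degrees(np.arctan2(-ny, -nx)) + rng.normal(0, 5)
            nx = x + speed * dt * np.cos(np.radians(heading))
            ny = y + speed * dt * np.sin(np.radians(heading))
        x, y = nx, ny
    return pd.DataFrame(rows, columns=["time_s", "x_mm", "y_mm",
                                       "heading_deg", "speed_mms"])


def _render_behavior_frames(p: BehaviorSimParams, truth: pd.DataFrame) -> np.ndarray:
    rng = np.random.default_rng(p.seed + 1)
    dish_d_px = p.dish_diameter_mm * p.px_per_mm
    margin = int(round(0.12 * dish_d_px))
    w = int(round(dish_d_px)) + 2 * margin
    h = int(round(dish_d_px)) + 2 * margin
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy)
    base = np.full((h, w), 120.0)                      # stage outside the dish
    inside = r <= dish_d_px / 2.0
    base[inside] = 190.0                               # bright dish interior
    ring = np.abs(r - dish_d_px / 2.0) <= 1.5
    base[ring] = 60.0                                  # dark dish boundary

    a = p.tadpole_major_mm * p.px_per_mm / 2.0
    b = p.tadpole_minor_mm * p.px_per_mm / 2.0
    frames = np.empty((len(truth), h, w), dtype=np.uint8)
    for i, row in enumerate(truth.itertuples()):
        img = base.copy()
        px = cx + row.x_mm * p.px_per_mm
        py = cy + row.y_mm * p.px_per_mm
        th = np.radians(row.heading_deg)
        x0, x1 = int(max(0, px - a - 2)), int(min(w, px + a + 3))
        y0, y1 = int(max(0, py - a - 2)), int(min(h, py + a + 3))
        sx = xx[y0:y1, x0:x1] - px
        sy = yy[y0:y1, x0:x1] - py
        u = sx * np.cos(th) + sy * np.sin(th)
        v = -sx * np.sin(th) + sy * np.cos(th)
        body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        patch = img[y0:y1, x0:x1]
        patch[body] = 40.0
        img[y0:y1, x0:x1] = patch
        if p.noise_sigma > 0:
            img = img + rng.normal(0, p.noise_sigma, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


def make_behavior_video(params: BehaviorSimParams) -> Tuple[np.ndarray, pd.DataFrame, Dict]:
    """Render a behavior video; returns (frames, truth trajectory, meta).

    ``truth`` columns: time_s, x_mm, y_mm (dish-centered), heading_deg
    (unwrapped), speed_mms.  ``meta`` records the pixel geometry (dish center
    and px/mm) and the escape parameters.
    """
    truth = _simulate_trajectory(params)
    frames = _render_behavior_frames(params, truth)
    h, w = frames.shape[1:]
    meta = {
        "px_per_mm": params.px_per_mm,
        "dish_center_px": ((w - 1) / 2.0, (h - 1) / 2.0),
        "dish_diameter_px": params.dish_diameter_mm * params.px_per_mm,
        "fps": params.fps,
        "onset_s": params.onset_s,
        "escape": None if params.escape is None else vars(params.escape).copy(),
        "seed": params.seed,
    }
    return frames, truth, meta


# ---------------------------------------------------------------------------
# two-channel stacks

@dataclass
class StackSimParams:
    shape: Tuple[int, int, int] = (40, 128, 128)       # (z, y, x)
    voxel_um: Tuple[float, float, float] = (3.75, 1.2, 1.2)
    n_microglia: int = 6
    radius_vox: Tuple[float, float] = (4.0, 7.0)       # in-plane radius range
    z_radius_vox: Tuple[float, float] = (2.0, 3.5)
    red_intensity: float = 400.0
    red_background: float = 100.0
    green_baseline: float = 8.0                        # a: autofluorescence at 0 axons
    green_slope: float = 2.0                           # b: per-axon green content
    green_sigma: float = 4.0                           # per-animal noise on a + b*n
    n_axons: int = 4
    axon_brightness: float = 300.0
    axon_radius_vox: float = 1.5
    green_offset: float = 100.0                        # diffuse background (mode target)
    noise_sigma: float = 10.0
    seed: int = 0


def _place_blobs(rng: np.random.Generator, p: StackSimParams,
                 max_tries: int = 200) -> List[Tuple[np.ndarray, float, float]]:
    """Non-overlapping ellipsoid centers; (center, r_xy, r_z) per microglia."""
    nz, ny, nx = p.shape
    blobs: List[Tuple[np.ndarray, float, float]] = []
    for _ in range(p.n_microglia):
        for attempt in range(max_tries):
            r_xy = rng.uniform(*p.radius_vox)
            r_z = rng.uniform(*p.z_radius_vox)
            c = np.array([rng.uniform(r_z + 1, nz - r_z - 1),
                          rng.uniform(r_xy + 1, ny - r_xy - 1),
                          rng.uniform(r_xy + 1, nx - r_xy - 1)])
            if all(np.linalg.norm((c - c2) / [max(r_z, rz2), max(r_xy, rxy2),
                                              max(r_xy, rxy2)]) > 2.2
                   for c2, rxy2, rz2 in blobs):
                blobs.append((c, r_xy, r_z))
                break
        else:
            raise RuntimeError("could not place non-overlapping microglia; "
                               "reduce n_microglia or enlarge the volume")
    return blobs


def make_stack_pair(params: StackSimParams, animal_id: str = "animal",
                    day: int = 4) -> Tuple[StackPair, Dict]:
    """Synthesize a two-channel stack; returns (StackPair, ground truth).

    Truth holds the label volume, the per-blob green content (one shared
    draw of a + b*n_axons + eps per animal), the axon mask, the programmed
    (a, b) and the green offset.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    nz, ny, nx = p.shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)

    red = np.full(p.shape, p.red_background)
    green = np.full(p.shape, p.green_offset)
    labels = np.zeros(p.shape, dtype=np.int32)

    blobs = _place_blobs(rng, p)
    # green content shared per animal: one epsilon draw per stack
    content = p.green_baseline + p.green_slope * p.n_axons \
        + rng.normal(0, p.green_sigma)
    content = max(0.0, content)
    for lab, (c, r_xy, r_z) in enumerate(blobs, start=1):
        d2 = ((zz - c[0]) / r_z) ** 2 + ((yy - c[1]) / r_xy) ** 2 \
            + ((xx - c[2]) / r_xy) ** 2
        sel = d2 <= 1.0
        red[sel] = p.red_intensity
        green[sel] += content
        labels[sel] = lab

    # axons: bright random-walk tubes in the green channel, avoiding blobs
    axon_mask = np.zeros(p.shape, dtype=bool)
    for _ in range(p.n_axons):
        pos = np.array([rng.uniform(2, nz - 2), rng.uniform(2, ny - 2),
                        rng.uniform(2, nx - 2)])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rad = p.axon_radius_vox
        w = int(np.ceil(rad)) + 1
        for _ in range(int(2.0 * max(ny, nx))):
            z0, y0, x0 = pos
            zs = slice(max(0, int(z0) - w), min(nz, int(z0) + w + 1))
            ys = slice(max(0, int(y0) - w), min(ny, int(y0) + w + 1))
            xs = slice(max(0, int(x0) - w), min(nx, int(x0) + w + 1))
            d2 = ((zz[zs, ys, xs] - z0) ** 2 + (yy[zs, ys, xs] - y0) ** 2
                  + (xx[zs, ys, xs] - x0) ** 2)
            axon_mask[zs, ys, xs] |= d2 <= rad ** 2
            direction += 0.3 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
            if not ((1 < pos[0] < nz - 2) and (1 < pos[1] < ny - 2)
                    and (1 < pos[2] < nx - 2)):
                break
    axon_mask &= labels == 0   # keep tubes out of microglia so ROI means stay programmed
    green[axon_mask] = p.axon_brightness

    if p.noise_sigma > 0:
        red = red + rng.normal(0, p.noise_sigma, p.shape)
        green = green + rng.normal(0, p.noise_sigma, p.shape)
    red = np.clip(np.round(red), 0, 65535)
    green = np.clip(np.round(green), 0, 65535)

    pair = StackPair(red=red, green=green, voxel_um=p.voxel_um,
                     animal_id=animal_id, day=day)
    truth = {
        "labels": labels,
        "axon_mask": axon_mask,
        "green_content": content,
        "baseline_a": p.green_baseline,
        "slope_b": p.green_slope,
        "green_offset": p.green_offset,
        "n_axons": p.n_axons,
        "blob_sizes": [int((labels == l).sum()) for l in range(1, len(blobs) + 1)],
    }
    return pair, truth


# ---------------------------------------------------------------------------
# assay cohorts

def make_assay_cohort(n_animals: int = 47,
                      axon_count_range: Tuple[int, int] = (1, 10),
                      baseline_a: float = 8.0,
                      slope_day4: float = 1.0,
                      slope_day5: float = 2.0,
                      noise_sigma: float = 9.0,
                      animal_noise_frac: float = 0.5,
                      frac_blebbing: float = 0.0,
                      frac_axon_loss: float = 0.0,
                      condition: str = "control",
                      seed: int = 0,
                      image_mode: bool = False,
                      stack_params: Optional[StackSimParams] = None,
                      ) -> Tuple[List[TectumMeasurement], Dict]:
    """Day-4/day-5 cohort with day-dependent green~axon slopes.

    In table mode (default) the per-animal mean microglial green is drawn
    directly as a + b_day * axon_count + eps; the two days of one animal are
    paired measurements, so ``animal_noise_frac`` of the noise variance is a
    shared animal-level component and the rest is day-specific.  In image
    mode each measurement comes from a synthesized stack (slower, with
    independent per-stack noise).  ``frac_blebbing`` /
    ``frac_axon_loss`` flag a fraction of animals with blebbing or a day-5
    axon-count drop so exclusion rules can be exercised.  Truth records the
    programmed parameters and which animals were contaminated.
    """
    if n_animals < 8:
        raise ValueError("need at least 8 animals")
    lo, hi = axon_count_range
    rng = np.random.default_rng(seed)
    counts = rng.integers(lo, hi + 1, size=n_animals)
    if np.all(counts == counts[0]):
        import warnings
        warnings.warn("degenerate axon-count distribution: correlation undefined")
    n_bleb = int(round(frac_blebbing * n_animals))
    n_loss = int(round(frac_axon_loss * n_animals))
    flagged = rng.permutation(n_animals)[: n_bleb + n_loss]
    bleb_ids = set(flagged[:n_bleb].tolist())
    loss_ids = set(flagged[n_bleb:].tolist())

    sigma_animal = noise_sigma * np.sqrt(animal_noise_frac)
    sigma_day = noise_sigma * np.sqrt(1.0 - animal_noise_frac)
    measurements: List[TectumMeasurement] = []
    for i in range(n_animals):
        animal = f"{condition}_{i:03d}"
        eps_animal = rng.normal(0, sigma_animal)
        ax4 = int(counts[i])
        ax5 = ax4 - 1 if i in loss_ids and ax4 > lo else (ax4 if i not in loss_ids else ax4)
        if i in loss_ids and ax5 == ax4:          # count already at the floor
            ax4 = ax4 + 1
        for day, slope, ax in ((4, slope_day4, ax4), (5, slope_day5, ax5)):
            if image_mode:
                sp = stack_params or StackSimParams()
                sp = StackSimParams(**{**vars(sp),
                                       "green_baseline": baseline_a,
                                       "green_slope": slope,
                                       "green_sigma": noise_sigma,
                                       "n_axons": ax,
                                       "seed": int(rng.integers(0, 2**31 - 1))})
                from .trogo import measure_stack
                pair, _ = make_stack_pair(sp, animal_id=animal, day=day)
                _, meas = measure_stack(pair, axon_count=ax,
                                        blebbing=(i in bleb_ids),
                                        condition=condition,
                                        min_size=_min_size_for(sp))
                measurements.append(meas)
            else:
                green = baseline_a + slope * ax + eps_animal \
                    + rng.normal(0, sigma_day)
                measurements.append(TectumMeasurement(
                    animal_id=animal, day=day, axon_count=ax,
                    blebbing=(i in bleb_ids),
                    mean_microglial_green=float(green), n_rois=1,
                    condition=condition))
    truth = {
        "baseline_a": baseline_a,
        "slope_day4": slope_day4,
        "slope_day5": slope_day5,
        "noise_sigma": noise_sigma,
        "axon_counts": counts.tolist(),
        "blebbing_animals": sorted(f"{condition}_{i:03d}" for i in bleb_ids),
        "axon_loss_animals": sorted(f"{condition}_{i:03d}" for i in loss_ids),
    }
    return measurements, truth


def _min_size_for(sp: StackSimParams) -> int:
    """A size cutoff proportionate to the scaled-down synthetic blobs."""
    r_min = sp.radius_vox[0]
    return max(50, int(0.5 * (4.0 / 3.0) * np.pi * r_min ** 2 * sp.z_radius_vox[0]))


# ---------------------------------------------------------------------------
# real-time series

def make_realtime_series(n_frames: int = 20, interval_s: float = 360.0,
                         base_level: float = 20.0, fold: float = 3.0,
                         event_frame: int = 16, noise_sigma: float = 0.0,
                         shape: Tuple[int, int, int] = (16, 48, 48),
                         drift_vox: float = 0.5,
                         seed: int = 0) -> Tuple[List[np.ndarray], List[np.ndarray], Dict]:
    """One slowly moving microglial blob whose green content steps at ``event_frame``.

    Returns (red series, green series, truth); the red blob is constant and
    well above background, the green content inside the blob steps from
    ``base_level`` to ``base_level * fold``.
    """
    if n_frames < 16:
        raise ValueError("need at least 16 frames")
    if event_frame <= 1:
        raise ValueError("event_frame must be > 1 (baseline undefined otherwise)")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    c = np.array([nz / 2.0, ny / 3.0, nx / 3.0])  # off-center: the rotated-
    # stack background footprint must land on background, not the blob itself
    r = min(nz, ny, nx) / 4.0
    reds, greens = [], []
    for i in range(n_frames):
        center = c + drift_vox * rng.normal(size=3)
        d2 = ((zz - center[0]) / (r / 2)) ** 2 + ((yy - center[1]) / r) ** 2 \
            + ((xx - center[2]) / r) ** 2
        blob = d2 <= 1.0
        red = np.where(blob, 400.0, 100.0)
        level = base_level * (fold if i >= event_frame else 1.0)
        green = np.where(blob, 50.0 + level, 50.0)
        if noise_sigma > 0:
            red = red + rng.normal(0, noise_sigma, shape)
            green = green + rng.normal(0, noise_sigma, shape)
        reds.append(red)
        greens.append(green)
    truth = {"base_level": base_level, "fold": fold, "event_frame": event_frame,
             "interval_s": interval_s}
    return reds, greens, truth


# ---------------------------------------------------------------------------
# colocalization pairs

def make_coloc_pair(shape: Tuple[int, int, int] = (16, 64, 64),
                    rho: float = 0.9, seed: int = 0,
                    fg_mean: float = 150.0, fg_sigma: float = 30.0,
                    bg_mean: float = 40.0, bg_sigma: float = 8.0,
                    ) -> Tuple[np.ndarray, np.ndarray, Dict]:
    """Two volumes with jointly Gaussian foreground voxels at correlation ``rho``.

    The foreground is a central ellipsoidal blob; the background is
    independent noise in both channels.  Intensities are rounded to integers
    (Costes scans unit steps) and clipped at 0.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    fg = (((zz - nz / 2) / (nz / 3)) ** 2 + ((yy - ny / 2) / (ny / 3)) ** 2
          + ((xx - nx / 2) / (nx / 3)) ** 2) <= 1.0
    n_fg = int(fg.sum())
    u = rng.normal(size=n_fg)
    v = rho * u + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=n_fg)
    ch1 = rng.normal(bg_mean, bg_sigma, shape)
    ch2 = rng.normal(bg_mean, bg_sigma, shape)
    ch1[fg] = fg_mean + fg_sigma * u
    ch2[fg] = fg_mean + fg_sigma * v
    ch1 = np.clip(np.round(ch1), 0, None)
    ch2 = np.clip(np.round(ch2), 0, None)
    truth = {"rho": rho, "foreground_mask": fg, "n_foreground": n_fg}
    return ch1, ch2, truth
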