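"""Microglial trogocytosis quantification on two-channel 3D stacks.

Microglia (red channel) are segmented as 26-connected components above a
mean + k*SD intensity threshold with a minimum object size; the green (axon
fluorophore) signal inside each microglial ROI is measured after subtracting
the stack-wide modal green intensity; ROIs overlapping the axon mask or
manually flagged are excluded; per-animal day-4/day-5 measurements are
assembled into an assay table with the blebbing / axon-loss exclusion rule;
and the green~axon-count relationship is summarized per day by Pearson
correlation, the day-5 minus day-4 change, and Fisher r-to-z comparisons
between conditions.  Real-time traces (fixed-threshold ROI regenerated per
timepoint, rotated-stack background, baseline from the first 15 pre-
interaction frames) and nearest-neighbor microglia mobility tracking round
out the assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import fisher_z_compare, pearson_with_test

log = logging.getLogger(__name__)

__all__ = [
    "StackPair",
    "MicrogliaROI",
    "TectumMeasurement",
    "AssayTable",
    "RealtimeTrace",
    "MobilityTrack",
    "hybrid_median_3d",
    "register_series",
    "segment_microglia",
    "green_mode_background",
    "measure_rois",
    "derive_axon_mask",
    "assemble_assay",
    "assay_correlations",
    "realtime_roi_trace",
    "link_microglia",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StackPair:
    """Two-channel volume: red = microglia label, green = axonal fluorophore."""

    red: np.ndarray
    green: np.ndarray
    voxel_um: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x)
    animal_id: str = "animal"
    day: int = 4

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        if self.red.shape != self.green.shape:
            raise ValueError("red and green volumes must have the same shape")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be > 0")


@dataclass
class MicrogliaROI:
    label: int
    n_voxels: int
    bbox: Tuple[slice, ...]
    mean_green_raw: float
    mean_green_corrected: float
    excluded: bool = False
    exclusion_reason: str = "none"  # none | axon_overlap | manual


@dataclass
class TectumMeasurement:
    animal_id: str
    day: int
    axon_count: int
    blebbing: bool
    mean_microglial_green: float
    n_rois: int
    condition: str = "control"


@dataclass
class AssayTable:
    """Paired day-4/day-5 measurements per animal after optional exclusions.

    ``data`` columns: animal_id, condition, axon_count_d4, axon_count_d5,
    blebbing_d4, blebbing_d5, green_d4, green_d5, excluded, exclusion_reason.
    """

    data: pd.DataFrame = field(repr=False)
    exclusion_rule_enabled: bool = True

    @property
    def included(self) -> pd.DataFrame:
        return self.data[~self.data["excluded"]]


@dataclass
class RealtimeTrace:
    time_s: np.ndarray
    values: np.ndarray               # background-subtracted ROI green means
    baseline: float
    fold_change: np.ndarray
    interaction_frame: Optional[int] = None


@dataclass
class MobilityTrack:
    points_um: np.ndarray            # (k, 3) centroid sequence, µm
    timepoints: np.ndarray           # timepoint indices
    mean_speed_um_min: float
    gap_count: int = 0


# ---------------------------------------------------------------------------
# filtering / registration

def hybrid_median_3d(volume: np.ndarray) -> np.ndarray:
    """3D hybrid median filter for impulse-noise rejection.

    Each output voxel is the median of four values: the medians of the three
    axis-aligned 3x3 neighborhoods through the voxel (xy, xz and yz planes)
    and the voxel itself.  Edges are handled by reflection padding.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("hybrid_median_3d needs a 3D volume; use a 2D median "
                         "filter for planar images")
    if min(vol.shape) < 3:
        raise ValueError("each axis must have at least 3 voxels")
    foot_xy = np.zeros((1, 3, 3), dtype=bool); foot_xy[0] = True
    foot_xz = np.zeros((3, 1, 3), dtype=bool); foot_xz[:, 0, :] = True
    foot_yz = np.zeros((3, 3, 1), dtype=bool); foot_yz[:, :, 0] = True
    m_xy = ndimage.median_filter(vol, footprint=foot_xy, mode="mirror")
    m_xz = ndimage.median_filter(vol, footprint=foot_xz, mode="mirror")
    m_yz = ndimage.median_filter(vol, footprint=foot_yz, mode="mirror")
    return np.median(np.stack([m_xy, m_xz, m_yz, vol]), axis=0)


def register_series(volumes: Sequence[np.ndarray],
                    search_radius: int = 5) -> Tuple[List[Tuple[int, int, int]], List[np.ndarray]]:
    """Align a time series of volumes to the first by integer 3D translation.

    The shift maximizing the (FFT) cross-correlation with the reference is
    searched within ``search_radius`` voxels per axis; shifts on the search
    boundary trigger an under-registration warning.  Returns the recovered
    shifts (applied volume -> reference) and the shifted volumes.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to register")
    ref = np.asarray(volumes[0], dtype=float)
    ref_c = ref - ref.mean()
    f_ref = np.fft.rfftn(ref_c)
    shifts: List[Tuple[int, int, int]] = []
    aligned: List[np.ndarray] = [np.asarray(volumes[0]).copy()]
    for vol in volumes[1:]:
        v = np.asarray(vol, dtype=float)
        if v.shape != ref.shape:
            raise ValueError("all volumes must have the same shape")
        cc = np.fft.irfftn(f_ref * np.conj(np.fft.rfftn(v - v.mean())),
                           s=ref.shape, axes=(0, 1, 2))
        best, best_val = (0, 0, 0), -np.inf
        for dz in range(-search_radius, search_radius + 1):
            for dy in range(-search_radius, search_radius + 1):
                for dx in range(-search_radius, search_radius + 1):
                    val = cc[dz % ref.shape[0], dy % ref.shape[1], dx % ref.shape[2]]
                    if val > best_val:
                        best_val, best = val, (dz, dy, dx)
        if any(abs(s) == search_radius for s in best):
            log.warning("registration shift %s on the search boundary "
                        "(radius %d); possible under-registration", best, search_radius)
        shifts.append(best)
        aligned.append(np.roll(np.asarray(vol), best, axis=(0, 1, 2)))
    return shifts, aligned


# ---------------------------------------------------------------------------
# segmentation and measurement

def segment_microglia(red: np.ndarray, k_sd: float = 2.0,
                      min_size: int = 1500) -> np.ndarray:
    """Label microglia as 26-connected components of red > mean + k_sd * SD.

    The threshold statistics are taken over the entire stack (background
    included).  Components smaller than ``min_size`` voxels are discarded and
    surviving labels are renumbered 1..K by descending voxel count.
    """
    red = np.asarray(red, dtype=float)
    if red.size == 0:
        raise ValueError("empty volume")
    thr = red.mean() + k_sd * red.std()
    mask = red > thr
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        log.warning("no voxels above threshold %.1f", thr)
        return labels
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.nonzero(sizes >= min_size)[0]
    if keep.size == 0:
        log.warning("no component reached min_size=%d voxels", min_size)
        return np.zeros_like(labels)
    # descending size, deterministic tie-break on the original label index
    order = sorted(keep, key=lambda l: (-sizes[l], l))
    out = np.zeros_like(labels)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def green_mode_background(green: np.ndarray) -> float:
    """Most frequent (integer-rounded) green intensity; ties -> lowest value."""
    g = np.asarray(green)
    vals = np.round(g.ravel()).astype(np.int64)
    offset = vals.min()
    counts = np.bincount(vals - offset)
    return float(np.argmax(counts) + offset)  # argmax returns first (lowest) tie


def measure_rois(labels: np.ndarray, green: np.ndarray, mode_bg: float,
                 axon_mask: Optional[np.ndarray] = None,
                 manual_exclusions: Sequence[int] = ()) -> Tuple[List[MicrogliaROI], float]:
    """Background-corrected mean green per microglial ROI, plus the summary.

    Per ROI: mean(green) - mode_bg, clamped at 0.  ROIs sharing any voxel
    with ``axon_mask`` are excluded (reason ``axon_overlap``); ids in
    ``manual_exclusions`` are excluded (reason ``manual``).  The summary is
    the unweighted mean over included ROIs; raises when none remain.
    """
    labels = np.asarray(labels)
    green = np.asarray(green, dtype=float)
    if labels.shape != green.shape:
        raise ValueError("labels and green must have the same shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no ROIs to measure")
    objects = ndimage.find_objects(labels)
    manual = set(int(i) for i in manual_exclusions)
    rois: List[MicrogliaROI] = []
    for lab in ids:
        sel = labels == lab
        raw = float(green[sel].mean())
        corrected = max(0.0, raw - mode_bg)
        reason = "none"
        if int(lab) in manual:
            reason = "manual"
        elif axon_mask is not None and bool(np.any(sel & np.asarray(axon_mask, bool))):
            reason = "axon_overlap"
        rois.append(MicrogliaROI(label=int(lab), n_voxels=int(sel.sum()),
                                 bbox=objects[lab - 1],
                                 mean_green_raw=raw,
                                 mean_green_corrected=corrected,
                                 excluded=reason != "none",
                                 exclusion_reason=reason))
    included = [r.mean_green_corrected for r in rois if not r.excluded]
    if not included:
        raise ValueError("all ROIs excluded; no population summary")
    return rois, float(np.mean(included))


def derive_axon_mask(green: np.ndarray, k_sd: float = 2.0) -> np.ndarray:
    """Axon mask from the green channel by the same mean + k*SD rule."""
    g = np.asarray(green, dtype=float)
    return g > g.mean() + k_sd * g.std()


def measure_stack(pair: StackPair, k_sd: float = 2.0, min_size: int = 1500,
                  axon_mask: Optional[np.ndarray] = None,
                  manual_exclusions: Sequence[int] = (),
                  axon_count: int = 0, blebbing: bool = False,
                  condition: str = "control") -> Tuple[List[MicrogliaROI], TectumMeasurement]:
    """Segment + measure one stack into a :class:`TectumMeasurement`."""
    labels = segment_microglia(pair.red, k_sd=k_sd, min_size=min_size)
    mode_bg = green_mode_background(pair.green)
    rois, summary = measure_rois(labels, pair.green, mode_bg, axon_mask,
                                 manual_exclusions)
    n_inc = sum(1 for r in rois if not r.excluded)
    meas = TectumMeasurement(animal_id=pair.animal_id, day=pair.day,
                             axon_count=axon_count, blebbing=blebbing,
                             mean_microglial_green=summary, n_rois=n_inc,
                             condition=condition)
    return rois, meas


# ---------------------------------------------------------------------------
# assay assembly and inference

def assemble_assay(measurements: Sequence[TectumMeasurement],
                   exclusion_rule_enabled: bool = True) -> AssayTable:
    """Pair day-4/day-5 measurements per animal and apply the exclusion rule.

    With the rule enabled, an animal is excluded iff blebbing was flagged on
    either day or its labeled-axon count fell from day 4 to day 5 (the rule
    is disabled for synaptophysin-targeted label, where puncta counts are not
    comparable across days).  Animals missing a day are dropped with a
    warning.
    """
    by_animal: Dict[str, Dict[int, TectumMeasurement]] = {}
    for m in measurements:
        by_animal.setdefault(m.animal_id, {})[m.day] = m
    rows = []
    for animal, days in by_animal.items():
        if 4 not in days or 5 not in days:
            log.warning("animal %s missing day %s; dropped",
                        animal, 4 if 4 not in days else 5)
            continue
        d4, d5 = days[4], days[5]
        excluded, reason = False, "none"
        if exclusion_rule_enabled:
            if d4.blebbing or d5.blebbing:
                excluded, reason = True, "blebbing"
            elif d5.axon_count < d4.axon_count:
                excluded, reason = True, "axon_loss"
        rows.append({
            "animal_id": animal,
            "condition": d4.condition,
            "axon_count_d4": d4.axon_count,
            "axon_count_d5": d5.axon_count,
            "blebbing_d4": d4.blebbing,
            "blebbing_d5": d5.blebbing,
            "green_d4": d4.mean_microglial_green,
            "green_d5": d5.mean_microglial_green,
            "excluded": excluded,
            "exclusion_reason": reason,
        })
    return AssayTable(data=pd.DataFrame(rows),
                      exclusion_rule_enabled=exclusion_rule_enabled)


def assay_correlations(table: AssayTable,
                       other: Optional[AssayTable] = None) -> Dict[str, object]:
    """Per-day Pearson correlations of microglial green vs axon count.

    Returns day-4 and day-5 :class:`~xenassay.stats.CorrelationResult`s, the
    day-to-day change (green_d5 - green_d4 vs day-5 axon count), and, when a
    second condition's table is supplied, Fisher r-to-z comparisons of the
    delta correlation (and per-day correlations) between conditions.
    """
    df = table.included
    if len(df) < 4:
        raise ValueError(f"need >= 4 included animals, got {len(df)}")
    res: Dict[str, object] = {
        "day4": pearson_with_test(df["axon_count_d4"], df["green_d4"]),
        "day5": pearson_with_test(df["axon_count_d5"], df["green_d5"]),
        "delta": pearson_with_test(df["axon_count_d5"],
                                   df["green_d5"] - df["green_d4"]),
        "n": len(df),
    }
    if other is not None:
        odf = other.included
        if len(odf) < 4:
            raise ValueError("comparison condition has < 4 included animals")
        o_delta = pearson_with_test(odf["axon_count_d5"],
                                    odf["green_d5"] - odf["green_d4"])
        res["delta_other"] = o_delta
        res["fisher_z_delta"] = fisher_z_compare(
            res["delta"].r, res["delta"].n, o_delta.r, o_delta.n)
        o_d5 = pearson_with_test(odf["axon_count_d5"], odf["green_d5"])
        res["fisher_z_day5"] = fisher_z_compare(
            res["day5"].r, res["day5"].n, o_d5.r, o_d5.n)
    return res


# ---------------------------------------------------------------------------
# real-time imaging

def _rotate180_inplane(volume: np.ndarray) -> np.ndarray:
    return volume[:, ::-1, ::-1]


def _mirror_inplane(volume: np.ndarray) -> np.ndarray:
    return volume[:, :, ::-1]


def realtime_roi_trace(red_series: Sequence[np.ndarray],
                       green_series: Sequence[np.ndarray],
                       fixed_threshold: float,
                       min_size: int = 50,
                       interaction_frame: Optional[int] = None,
                       interval_s: float = 360.0,
                       baseline_frames: int = 15,
                       background: str = "rotate") -> RealtimeTrace:
    """Green-fluorescence fold-change of one microglial ROI over time.

    At each timepoint the ROI is regenerated as the largest 26-connected red
    component above the same ``fixed_threshold``; the value is the green mean
    inside the ROI minus the green mean of the ROI footprint applied to the
    in-plane 180-degree-rotated (or mirrored) green stack.  The baseline is
    the mean of the first ``baseline_frames`` values, truncated at
    ``interaction_frame`` when a microglial interaction occurs earlier, and
    the trace is reported as value / baseline.
    """
    n = len(red_series)
    if n != len(green_series):
        raise ValueError("red and green series must have equal length")
    if n < baseline_frames + 1 and interaction_frame is None:
        raise ValueError(f"need >= {baseline_frames + 1} timepoints for the "
                         "default baseline rule")
    if interaction_frame is not None and interaction_frame <= 1:
        raise ValueError("baseline undefined: interaction at or before the first frame")
    flip = _rotate180_inplane if background == "rotate" else _mirror_inplane
    values = np.empty(n)
    for i in range(n):
        red = np.asarray(red_series[i], dtype=float)
        green = np.asarray(green_series[i], dtype=float)
        mask = red > fixed_threshold
        labels, nl = ndimage.label(mask, structure=_STRUCT_26)
        if nl == 0:
            values[i] = np.nan
            continue
        sizes = np.bincount(labels.ravel()); sizes[0] = 0
        lab = int(np.argmax(sizes))
        if sizes[lab] < min_size:
            values[i] = np.nan
            continue
        roi = labels == lab
        values[i] = green[roi].mean() - flip(green)[roi].mean()
    k = baseline_frames if interaction_frame is None else min(baseline_frames,
                                                              interaction_frame)
    base_vals = values[:k]
    baseline = float(np.nanmean(base_vals))
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError("fold-change undefined: baseline <= 0 or missing")
    return RealtimeTrace(time_s=np.arange(n) * interval_s, values=values,
                         baseline=baseline, fold_change=values / baseline,
                         interaction_frame=interaction_frame)


# ---------------------------------------------------------------------------
# mobility

def link_microglia(centroids_per_timepoint: Sequence[np.ndarray],
                   interval_s: float = 360.0,
                   max_displacement_um: float = 40.0,
                   min_track_timepoints: int = 5) -> Tuple[List[MobilityTrack], float]:
    """Greedy mutual-nearest-neighbor linking of microglia centroids (µm).

    Detections in consecutive timepoints are linked when each is the other's
    nearest neighbor and their distance is below ``max_displacement_um``;
    unmatched detections start or end tracks.  Per-track mean speed is the
    summed step length over elapsed minutes; the cohort mean is taken over
    tracks spanning at least ``min_track_timepoints`` timepoints.
    """
    if len(centroids_per_timepoint) < 2:
        raise ValueError("need at least 2 timepoints")
    pts = [np.asarray(c, dtype=float).reshape(-1, 3)
           for c in centroids_per_timepoint]
    # open tracks: list of (point indices per timepoint, coordinates)
    tracks: List[List[Tuple[int, np.ndarray]]] = [[(0, p)] for p in pts[0]]
    open_idx = list(range(len(tracks)))
    for t in range(1, len(pts)):
        cur = pts[t]
        prev_pts = np.array([tracks[i][-1][1] for i in open_idx]).reshape(-1, 3)
        linked_cur = set()
        next_open = []
        if len(prev_pts) and len(cur):
            d = np.linalg.norm(prev_pts[:, None, :] - cur[None, :, :], axis=2)
            nn_fwd = np.argmin(d, axis=1)
            nn_bwd = np.argmin(d, axis=0)
            for a, i_track in enumerate(open_idx):
                b = nn_fwd[a]
                if nn_bwd[b] == a and d[a, b] <= max_displacement_um:
                    tracks[i_track].append((t, cur[b]))
                    linked_cur.add(int(b))
                    next_open.append(i_track)
        for b, p in enumerate(cur):
            if b not in linked_cur:
                tracks.append([(t, p)])
                next_open.append(len(tracks) - 1)
        open_idx = next_open
    out: List[MobilityTrack] = []
    speeds = []
    for tr in tracks:
        tp = np.array([e[0] for e in tr])
        xyz = np.array([e[1] for e in tr])
        if len(tr) < 2:
            out.append(MobilityTrack(points_um=xyz, timepoints=tp,
                                     mean_speed_um_min=0.0))
            continue
        path = float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
        minutes = (tp[-1] - tp[0]) * interval_s / 60.0
        speed = path / minutes if minutes > 0 else 0.0
        gaps = int(np.sum(np.diff(tp) > 1))
        out.append(MobilityTrack(points_um=xyz, timepoints=tp,
                                 mean_speed_um_min=speed, gap_count=gaps))
        if len(tr) >= min_track_timepoints:
            speeds.append(speed)
    cohort = float(np.mean(speeds)) if speeds else float("nan")
    return out, cohort
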