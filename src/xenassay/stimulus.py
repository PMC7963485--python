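"""Parametric looming-stimulus model and renderer.

A looming stimulus is a centered disc whose diameter grows exponentially
(default +10% per frame at 60 fps) from a small seed diameter until the disc
covers the projected frame, is held full-screen for a fixed interval, and is
then reset, followed by a refractory period before the next trial.  The
geometry is kept exact (real-valued diameters); rasterization happens only at
render time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "LoomTimeline",
    "diameter_at_frame",
    "coverage_diameter_px",
    "frames_to_full_screen",
    "time_to_full_screen",
    "build_timeline",
    "render_frames",
]

#: luminance metadata (cd/m^2) of the disc and field for dark polarity;
#: swapped for bright polarity
_DARK_FG_CDM2 = 29.0
_DARK_BG_CDM2 = 208.0


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one looming-stimulus presentation.

    ``polarity`` selects a dark disc on a light field (``"dark"``) or the
    inverse (``"bright"``).  The luminances are carried as metadata only; the
    renderer maps them to configurable 8-bit gray levels because the package
    cannot reproduce a projector's photometry.
    """

    polarity: str = "dark"
    frame_width_px: int = 800
    frame_height_px: int = 600
    screen_width_cm: float = 10.6
    screen_height_cm: float = 8.0
    initial_diameter_px: float = 54.0
    growth_per_frame: float = 0.10
    fps: float = 60.0
    hold_s: float = 0.8
    refractory_s: float = 10.0
    fg_luminance_cdm2: Optional[float] = None
    bg_luminance_cdm2: Optional[float] = None
    #: how "encompasses the screen" is judged: the centered circle must cover
    #: the frame diagonal (all four corners; default), or only its width/height
    coverage: str = "diagonal"
    #: disc center in px; None means frame center
    center_px: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"polarity must be 'dark' or 'bright', got {self.polarity!r}")
        if self.coverage not in ("diagonal", "width", "height"):
            raise ValueError(f"unknown coverage criterion {self.coverage!r}")
        for name in ("frame_width_px", "frame_height_px", "initial_diameter_px",
                     "growth_per_frame", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hold_s < 0 or self.refractory_s < 0:
            raise ValueError("hold_s and refractory_s must be >= 0")
        if self.fg_luminance_cdm2 is None:
            fg = _DARK_FG_CDM2 if self.polarity == "dark" else _DARK_BG_CDM2
            object.__setattr__(self, "fg_luminance_cdm2", fg)
        if self.bg_luminance_cdm2 is None:
            bg = _DARK_BG_CDM2 if self.polarity == "dark" else _DARK_FG_CDM2
            object.__setattr__(self, "bg_luminance_cdm2", bg)

    @property
    def px_per_mm(self) -> float:
        """Projection scale from the physical screen size (800 px <-> 10.6 cm)."""
        return self.frame_width_px / (self.screen_width_cm * 10.0)

    def px_to_mm(self, px: float) -> float:
        return px / self.px_per_mm


@dataclass(frozen=True)
class LoomTimeline:
    """Frame-by-frame realization of a :class:`StimulusSpec`.

    ``frames`` has columns ``frame``, ``time_s``, ``diameter_px`` and
    ``phase`` (``expanding``/``hold``/``reset``); diameters are the exact
    model values, uncapped, strictly increasing during expansion.
    """

    frames: pd.DataFrame = field(repr=False)
    n_expansion_frames: int
    time_to_full_screen_s: float

    def __len__(self) -> int:
        return len(self.frames)


def diameter_at_frame(spec: StimulusSpec, n) -> float:
    """Disc diameter (px) at expansion frame ``n``: d0 * (1 + g)^n, uncapped."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("frame index must be >= 0")
    d = spec.initial_diameter_px * (1.0 + spec.growth_per_frame) ** n_arr
    return float(d) if np.isscalar(n) or n_arr.ndim == 0 else d


def coverage_diameter_px(spec: StimulusSpec) -> float:
    """Diameter at which the centered disc covers the frame under the spec's criterion."""
    if spec.coverage == "diagonal":
        return math.hypot(spec.frame_width_px, spec.frame_height_px)
    if spec.coverage == "width":
        return float(spec.frame_width_px)
    return float(spec.frame_height_px)


def frames_to_full_screen(spec: StimulusSpec) -> int:
    """Smallest n with diameter_at_frame(n) >= the coverage diameter."""
    target = coverage_diameter_px(spec)
    if spec.initial_diameter_px >= target:
        return 0
    # closed form, then correct for float rounding at the boundary
    n = math.ceil(math.log(target / spec.initial_diameter_px)
                  / math.log1p(spec.growth_per_frame))
    while n > 0 and diameter_at_frame(spec, n - 1) >= target:
        n -= 1
    while diameter_at_frame(spec, n) < target:
        n += 1
    return n


def time_to_full_screen(spec: StimulusSpec) -> float:
    """Seconds from loom onset until the disc first covers the frame."""
    return frames_to_full_screen(spec) / spec.fps


def build_timeline(spec: StimulusSpec) -> LoomTimeline:
    """Expansion frames until coverage, then hold frames, then a reset marker."""
    n_exp = frames_to_full_screen(spec)
    n_hold = int(round(spec.hold_s * spec.fps))
    records = []
    for n in range(n_exp):
        records.append((n, n / spec.fps, diameter_at_frame(spec, n), "expanding"))
    d_full = diameter_at_frame(spec, n_exp)
    for k in range(n_hold):
        f = n_exp + k
        records.append((f, f / spec.fps, d_full, "hold"))
    f = n_exp + n_hold
    records.append((f, f / spec.fps, 0.0, "reset"))
    frames = pd.DataFrame(records, columns=["frame", "time_s", "diameter_px", "phase"])
    return LoomTimeline(frames=frames, n_expansion_frames=n_exp,
                        time_to_full_screen_s=n_exp / spec.fps)


def _gray_levels(spec: StimulusSpec, fg_gray: Optional[int], bg_gray: Optional[int]) -> Tuple[int, int]:
    if fg_gray is None:
        fg_gray = 30 if spec.polarity == "dark" else 220
    if bg_gray is None:
        bg_gray = 220 if spec.polarity == "dark" else 30
    return int(fg_gray), int(bg_gray)


def render_frames(spec: StimulusSpec, timeline: LoomTimeline,
                  fg_gray: Optional[int] = None,
                  bg_gray: Optional[int] = None) -> Iterator[np.ndarray]:
    """Yield 8-bit grayscale frames realizing ``timeline``.

    Gray levels are configurable proxies for the cd/m^2 metadata; reset frames
    show the bare background.
    """
    fg, bg = _gray_levels(spec, fg_gray, bg_gray)
    h, w = spec.frame_height_px, spec.frame_width_px
    cx, cy = spec.center_px if spec.center_px is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    for _, row in timeline.frames.iterrows():
        frame = np.full((h, w), bg, dtype=np.uint8)
        if row["phase"] != "reset":
            frame[r2 <= (row["diameter_px"] / 2.0) ** 2] = fg
        yield frame
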