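# xenassay

Quantitative pipelines for two in vivo assays used to study how microglia
sculpt developing retinotectal circuits in *Xenopus laevis* tadpoles:

1. **Looming-stimulus escape assay** — a dark or bright disc expands
   exponentially (10%/frame at 60 fps, from a 54 px ≈ 7 mm seed until it
   covers the projected frame ~0.5 s later) while a free-swimming tadpole in
   a 60 mm dish is videoed.  The package models the stimulus geometry,
   tracks the animal (dish-based scale calibration, temporal-median
   background subtraction, threshold segmentation, moments-based ellipse
   fit, motion-resolved unwrapped heading), and scores each trial: distance
   traveled 3 s before/after loom onset (trapezoidal area under the speed
   curve), escape distance and peak speed over 2 s, escape angle
   |Δheading| over a polarity-specific window (0.6 s dark / 1.2 s bright),
   a transparent positive/negative/undeterminable rule, and the response
   rate = positives / (positives + negatives).

2. **Microglial trogocytosis assay** — microglia nibble fluorescently
   labeled retinal ganglion cell axons, transferring pH-stable GFP into
   their phagocytic compartments.  From two-channel 3D stacks the package
   segments microglia (red > mean + 2·SD, 26-connected, ≥ 1500 voxels),
   measures mean green per ROI after subtracting the modal green intensity,
   applies the exclusion rules (axon-overlapping ROIs; animals with axonal
   blebbing or a day-4→day-5 drop in axon count), assembles paired
   day-4/day-5 tables, and quantifies the green ~ axon-count relationship
   with Pearson's r (two-sided t test, df = n − 2), compared across
   conditions by Fisher's r-to-z:

   z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))

   Real-time traces (fixed-threshold ROIs, rotated-stack background,
   baseline = mean of the first 15 pre-interaction frames), microglia
   mobility tracking, Costes automatic colocalization thresholds, and a
   Poisson fit to log-transformed histograms round out the toolbox.

Every pipeline input can be synthesized with recorded ground truth
(`xenassay.synthetic`), so tracking accuracy, ROI recovery and the
correlation inference are tested against known parameters end to end.

## Worked example

```python
from xenassay.synthetic import BehaviorSimParams, EscapeParams, make_behavior_video
from xenassay.tracking import track_video
from xenassay.behavior import TrialRecord, escape_metrics, classify_response

p = BehaviorSimParams(seed=0, escape=EscapeParams(turn_deg=60))
frames, truth, meta = make_behavior_video(p)      # 8 s video, loom at t = 4 s
traj = track_video(list(frames), p.fps)           # calibrate + track
trial = TrialRecord(traj, onset_s=p.onset_s, polarity="dark", trial_id="demo")
m = escape_metrics(trial)
print(classify_response(trial).label, m.escape_angle_deg)
```

prints (seed 0):

```
scale: 4.02 px/mm
pre/post distance: 6.0 / 21.6 mm
escape distance (2 s): 19.5 mm
max velocity: 34.9 mm/s
escape angle: 59.9 deg
label: positive -- post-onset travel 21.6 mm >= 12.0 mm (pre 6.0 mm)
```

The detected scale is within 1% of the programmed 4 px/mm; the escape angle
recovers the programmed 60° turn; the post-onset travel triples the
pre-onset travel, so the trial is scored as a defensive escape.

On the trogocytosis side, a table-mode cohort of 47 animals with a
day-dependent green ~ axon slope (day-5 slope twice day 4) gives

```
day4: r = 0.26, n = 47, p = 0.0748
day5: r = 0.55, n = 47, p = 0.0001
delta: r = 0.43, p = 0.0025
```

— a weak day-4 correlation that strengthens on day 5, the signature of
cumulative label transfer into microglia.

A CLI mirrors the library: `xenassay loom render`, `xenassay track run`,
`xenassay behavior metrics`, `xenassay trogo assay`, `xenassay stats
pearson|fisherz|costes`, `xenassay simulate video|stack|cohort`, `xenassay
run behavior|trogo`.  See `docs/methods.md` for the models, parameter
defaults and known limitations.

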