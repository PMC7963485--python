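# Methods

## Looming-stimulus geometry

The stimulus is a centered disc whose diameter grows geometrically,
d(n) = d₀ (1 + g)ⁿ, with defaults d₀ = 54 px and g = 0.10 per frame at
60 fps on an 800 × 600 px projection spanning 10.6 × 8 cm (so 54 px ≈ 7 mm).
"Encompassing the screen" is judged against the frame diagonal — the corners
are the last pixels a centered disc covers — giving 31 expansion frames
(0.52 s, 0.5 s at one decimal).  A width-coverage criterion is selectable
(`coverage="width"`, 29 frames = 0.48 s); both round to 0.5 s, and the
diagonal criterion is the default because it is the strict reading of full
coverage.  After expansion the frame is held full-screen for 0.8 s
(48 frames) and then reset, with a 10 s refractory period between trials.
Diameters are kept real-valued; rasterization happens only in the renderer,
whose gray levels are configurable proxies for the projector luminances
(29/208 cd/m², metadata only — a software artifact cannot reproduce
photometry).  The disc center defaults to the frame center and is
configurable.

## Video tracking

* **Scale.** The dish boundary is found as Canny edges fit by a RANSAC
  circle model, refined by a least-squares fit over all edge points within
  6 px of the consensus circle (a boundary of finite thickness contributes
  an inner and an outer edge ring; fitting both centers the estimate on the
  physical boundary).  px/mm = fitted diameter / 60 mm.  Calibration failure
  raises an error asking for a manual scale.
* **Background.** Per-pixel temporal median over ≤ 50 evenly spaced frames;
  robust as long as the animal occupies any given pixel in under half the
  sampled frames.
* **Segmentation.** |frame − background| is thresholded (Otsu by default, a
  fixed gray level by config), restricted to the dish interior; the largest
  8-connected component is kept (ties: lowest label), an empty mask marks
  the frame invalid.
* **Pose.** Moments-based ellipse fit: centroid, axes = 4√eigenvalues of the
  second-moment matrix, orientation = major-axis angle mod 180° in image
  coordinates (x right, y down, angles by atan2(dy, dx)).  Fewer than 5
  foreground pixels → invalid frame.
* **Heading.** The 180° ellipse ambiguity is resolved against the motion
  direction: where the animal moves faster than 0.5 mm/s the candidate
  (o or o + 180°) within 90° of the velocity direction is taken, otherwise
  the candidate continuous with the previous heading.  The velocity used
  here is an exponentially smoothed displacement (α = 0.4): single-frame
  displacements at drift speed carry sub-pixel centroid jitter that would
  flip the half-plane spuriously.  The result is unwrapped (cumulative).  If
  no frame ever exceeds the floor the series is flagged indeterminate.
* **Gaps.** Invalid runs of ≤ 3 frames are linearly interpolated and marked
  valid; longer gaps stay invalid.  More than 20% invalid frames logs a
  warning.

On synthetic videos (10 seeds) the tracker achieves centroid RMSE < 1 px
and recovers programmed escape turns within 5° (typically < 1°).

## Trial metrics and scoring

Speed is the central difference of the centroid (one-sided at the ends),
optionally smoothed by a 3-frame moving average; distances are trapezoidal
integrals of speed (`window_distance`), with pre/post windows of 3 s around
loom onset and the escape window 2 s.  The escape angle is
|heading(onset + w) − heading(onset)| on the unwrapped series, w = 0.6 s
for dark and 1.2 s for bright looms (matching the observed response
latencies of ≈ 0.5 s and ≈ 1.0 s), reflected into [0°, 180°].

The study scored responses with a blinded human rater; the package replaces
this with an explicit threshold rule whose constants live in
`ClassifierConfig` and whose decision is recorded per trial as a rationale
string: undeterminable if mean speed over the 0.5 s before onset exceeds
5 mm/s ("already moving quickly"); otherwise positive if post-onset travel
≥ max(5 mm, 2 × pre-onset travel); otherwise negative.  These defaults
separate synthetic burst/no-burst cohorts with sensitivity and specificity
≥ 0.9 but are *not* claimed to match any particular human rater — they are
placeholders to be calibrated against human scores when such data exist.

## Trogocytosis quantification

* **Denoising.** 3D hybrid median filter: each voxel becomes the median of
  {median of its 3×3 xy neighborhood, 3×3 xz, 3×3 yz, itself}; the median
  of this 4-element set averages the middle two values.  Boundaries use
  true reflection (numpy `reflect`).  Verified voxel-for-voxel against a
  brute-force oracle.
* **Registration.** Translation-only: integer shift maximizing FFT
  cross-correlation within a ±5 voxel search radius (boundary hits warn of
  under-registration).  Rotation between timepoints is assumed negligible —
  a deliberate simplification of descriptor-based registration.
* **Segmentation.** Threshold = mean + 2·SD of the red channel computed over
  the *entire* stack, background included (the stated rule names the whole
  channel; a per-slice option exists).  26-connected components ≥ 1500
  voxels are kept ("1500 pixels" is read as voxels of the acquired stack,
  irrespective of anisotropy; configurable), labeled by descending size.
* **Green measurement.** Diffuse background = mode of the integer-rounded
  green intensities (ties → lowest value); per-ROI value = mean green −
  mode, clamped at 0; ROIs sharing ≥ 1 voxel with the axon mask (supplied,
  or derived from green by the same mean + 2·SD rule) are excluded, as are
  listed manual exclusions (melanophores); the stack summary is the
  unweighted mean over included ROIs.
* **Assay table.** Animals need both day-4 and day-5 measurements.  With the
  exclusion rule enabled (pHtdGFP label), an animal is excluded iff blebbing
  was flagged on either day or the axon count fell from day 4 to day 5; the
  rule is disabled for SYP-targeted label.  Inference: Pearson r of mean
  microglial green vs axon count per day, the day-5 − day-4 green change vs
  day-5 axon count, and Fisher r-to-z contrasts between conditions.
* **Real-time traces.** The ROI is regenerated at a fixed threshold per
  timepoint; background is the green mean of the ROI footprint applied to
  the in-plane 180°-rotated stack (mirroring is a config switch; the
  original geometry is not specified, and rotation about the volume center
  keeps the footprint inside the tissue).  Baseline = mean of the first 15
  frames, truncated at the interaction frame; the trace is value/baseline.
* **Mobility.** Greedy mutual-nearest-neighbor linking of centroids at
  6 min intervals under a 40 µm step limit (an automatic stand-in for
  manual click-tracking); per-track speed = path length / elapsed minutes,
  cohort mean over tracks spanning ≥ 5 timepoints.

## Statistics

Pearson's r carries its exact two-sided test, t = r√(n−2)/√(1−r²) with
n − 2 df; `p_from_r_n` exposes the closed form so printed (r, n) pairs can
be checked against printed p-values.  The Fisher z comparison uses
SE = √(1/(n₁−3) + 1/(n₂−3)).  All tests are two-sided.

The Costes scan fits ch₂ = a·ch₁ + b by OLS (orthogonal regression
available) and lowers T₁ from max(ch₁) in unit intensity steps until the
correlation of the sub-threshold voxel pairs (ch₁ < T₁ and ch₂ < aT₁ + b)
reaches ≤ 0; r_above is the correlation above both thresholds.  For
uncorrelated channels the scan legitimately stops on the top bin, where
r_above may be undefined or the colocalized set empty.

"Poisson regression of log-transformed histograms" is implemented as a
maximum-likelihood Poisson fit to binned log-values: each value x maps to
bin k = ⌊ln x / w⌋ (default w = 0.25), the bin indices are modeled as
Poisson counts with λ̂ = their mean, and two samples are compared by
2(ℓ_separate − ℓ_pooled) against χ²(1).  When values below 1 produce
negative bins, indices are re-based at the lowest occupied bin (recorded in
the result) since the Poisson support is non-negative.  This is one
reading of an ambiguous description; the bin width is explicit so the fit
is reproducible.

## Synthetic data: what it does and does not emulate

The generators produce, deterministically per seed: behavior videos (dish
ring on a darker stage, drifting ellipse, escape burst with programmed
latency/peak/turn, exponential speed decay τ = 0.4 s, reflective walls,
Gaussian pixel noise σ = 3); two-channel stacks (ellipsoidal microglia at
red 400 over background 100, green content a + b·axon count + ε shared per
animal over a diffuse offset of 100, random-walk axon tubes, Gaussian noise
σ = 10); day-4/day-5 cohorts with day-specific slopes (defaults b₄ = 1,
b₅ = 2, σ = 9, axon counts uniform on 1–10, n = 47 — chosen so the
population correlations ≈ 0.30/0.53 match the weak-then-moderate structure
of the assay at its published sample size); real-time series with a
programmed fold step; and jointly Gaussian channel pairs at a programmed ρ.
Because the two days of one animal are paired measurements, half of the
cohort noise variance is a shared animal-level component
(`animal_noise_frac = 0.5`).

Stacks default to 40 × 128 × 128 voxels rather than acquisition-size
volumes; the minimum ROI size scales accordingly in tests
(`_min_size_for`).  The generators deliberately omit: optics (PSF,
attenuation with depth), tadpole body articulation (the animal is a rigid
ellipse; real escape C-bends momentarily break the ellipse model), pigment
cells, multi-animal scenes, and photon (Poisson) noise by default.  Passing
recovery tests therefore demonstrates correctness of the measurement
pipeline under its stated model, not robustness to every property of real
footage.

## Numerical choices and edge cases

Ties in the largest-component and mode computations resolve to the lowest
label/value for determinism.  The escape-speed peak recovered by central
differences underestimates an instantaneous burst by a few percent (finite
differencing integrates over two frames); tests allow 10%.  The parametric
Pearson p agrees with a seeded 10⁵-draw permutation null within 0.05 at
n = 8 — the permutation distribution is discrete (8! orderings), so exact
agreement is not expected; the type-I error at n = 20 is calibrated to
0.05 ± 0.01 over 10⁴ null replicates.  Degenerate inputs (zero variance,
empty masks, all-excluded ROIs, windows off the series) raise or flag
rather than returning silent numbers.

## Known limitations

Heading resolution assumes the body axis tracks the motion direction; a
true instantaneous ~180° reversal (wall rebound) produces a legitimate
half-turn step in the unwrapped series once the smoothed velocity catches
up.  The response classifier is a placeholder for human scoring.  The
Costes implementation follows the stated scan semantics with unit steps on
integer intensities; sub-unit thresholds are not searched.  MP4/AVI input
requires an imageio plugin able to open the container; PNG/TIFF frame
directories (with explicit fps) are the first-class input.
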