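# Methods

## Signals and model

The pipeline treats articulation as a set of goal-directed gestures,
each with an onset, target-holding and release phase.  Two observables
index them in mid-sagittal rtMRI video:

* **Oral constrictions** — the mean pixel intensity of a small fixed
  region at the constriction location.  MRI intensity is roughly
  proportional to tissue (proton density) in the voxel, so the series
  rises as the articulator fills the region and falls on release.
* **Vertical larynx position** — the intensity-weighted centroid of the
  larynx's connected component inside a fixed rectangular vocal-tract
  region (VTR), reported in mm above the VTR's bottom edge so that
  raising is positive.

Both are reduced to landmark times defined on the signal's velocity:
ONS and TONS at crossings of 20 % of the first toward-target velocity
peak (PVEL), MAX at the |velocity| minimum nearest the positional
extremum, TOFF at the crossing of 20 % of the release velocity peak.
Landmark times are interpolated linearly between frames because the
12 ms frame period is coarse relative to the lag differences of
interest.  A landmark that cannot be located sets a `found = False`
flag; the token-omission rule excludes such tokens per dependent
variable and logs per-consonant counts, mirroring how tokens without
quantifiable larynx movement are dropped in practice.

## Acquisition geometry

Defaults describe the source protocol: field of view 200 mm on an
84 × 84 grid (pixel 200/84 = 2.381 mm), TR 6.004 ms, 13 spiral
interleaves (one fully sampled image spans 78.052 ms), sliding-window
reconstruction over 2 TR giving 1000/(2 × 6.004) = 83.28 frames/s.

## Synthetic data

**Phantoms.**  Gestures follow a cosine ramp–hold–release trajectory
`A(1 − cos πt/T)/2`; it is smooth, has a single velocity peak per
movement phase (peak `Aπ/2T` at the midpoint), and its 20 % threshold
crossings have closed forms (`t₀ + (T/π)asin 0.2 ≈ t₀ + 0.0641 T`), so
landmark detection is analytically checkable.  The larynx is an
elliptical Gaussian blob (σ = radius/2) translated vertically by the
trajectory; the oral constriction is a fixed circular region whose
intensity scales with the normalised trajectory (tissue amount in the
region tracks constriction degree).  Distractor blobs exercise the
continuity rule.  Intensities are floats in [0, 1] to keep quantisation
away from the 20 % thresholds.  Noise is additive Gaussian by default
with magnitude (Rician) noise available; at the signal-to-noise ratios
of this protocol the Gaussian approximation is adequate for testing.
What the phantoms do *not* emulate: spiral k-space sampling, coil
profiles, reconstruction artifacts, through-plane motion, or real
anatomy — passing tests demonstrate the correctness of the kinematic
chain, not segmentation robustness on clinical images.

**Token tables.**  The study design is 3 speakers × 12 consonants
(3 ejectives, 3 voiceless pulmonics, 2 implosives, 2 voiced pulmonics,
2 nasals) × 2 prosodic conditions × 7 repetitions = 168 tokens per
speaker.  Each token's five measures are independent normal draws from
per-(speaker × class) cells whose default means/SDs are the published
group statistics; token omission is Bernoulli per (speaker, consonant)
with probability = reported omitted count / 14.  Cells the source does
not print are documented assumptions: larynx-movement durations are
drawn from within the reported 200–600 ms range (class means 350–450 ms,
SDs 70–100 ms); nasal-class magnitudes (−1.0 ± 2.5 mm displacement,
22 ± 4 mm extremum) and the lag distributions of voiceless pulmonics
and nasals (0 ± 130 ms onset, −120 ± 130 ms target) are plausible
values — those cells are excluded from the published lag analyses, so
nothing downstream depends on them.  Independence across measures
within a token is a simplification; real displacement/lag pairs are
correlated.

## Smoothing

* ROI series: locally weighted **linear** regression with a Gaussian
  kernel, bandwidth `kernel_width = 0.9` in units of the frame period.
  The bandwidth unit is a deliberate design choice: expressed instead
  as a fraction 0.9 of the series span, the smoother flattens a 250 ms
  gesture so completely that no 20 % onset crossing exists, whereas at
  0.9 frame periods it attenuates white noise SD by ~45 % while
  shifting the onset landmark by ~1 ms.
* Centroid tracks: locally weighted **quadratic** (loess) regression
  with tricube weights over a fixed span of 30 data points, applied to
  each axis.  Loess is linear in the response, so pixel and mm columns
  can be smoothed independently without inconsistency.  Invalid
  (dropout) frames are linearly interpolated before smoothing and stay
  flagged invalid.  On the cosine phantom this smoother leaves ≤ 1.2 %
  amplitude overshoot and a roughly one-frame onset bias — the dominant
  term in the end-to-end lag error (~14 ms worst case on the grid,
  inside the 1.5-frame tolerance).

## Segmentation and tracking choices

* Threshold: `fraction × robust max` of the VTR, robust max being the
  99.5th percentile; Otsu and absolute thresholds are available.  The
  default fraction is **0.2**: a cut half-way up the object's intensity
  profile discards boundary pixels that carry ~half the peak weight,
  which makes the component centroid oscillate by 0.1–0.2 px as the
  object translates sub-pixel; cutting at 0.2 keeps the low-intensity
  skirt and bounds that discretisation bias below 0.1 px (measured
  across Gaussian, supergaussian and partial-volume disk profiles) while
  still separating objects a few pixels apart.
* Connectivity 8; components enumerated in row-major label order, which
  is also the documented tie-break for equidistant centroids.
* Continuity: nearest-previous-centroid; frames with an empty component
  set are flagged invalid and the last valid centroid remains the
  reference, so tracking resumes after dropouts.
* "First maximum velocity" for PVEL is the first local maximum above a
  noise floor (default 5 % of the global |v| max); a raw first local
  maximum is noise-fragile.  The release reference for TOFF is the
  global away-from-target velocity peak after MAX, robust against
  small wiggles on the hold phase.  ONS uses the *last* 20 % crossing
  before PVEL (configurable).
* The TONS definition is applied unchanged to fricative-like gestures
  without a full closure plateau.

## Statistics

* Group tables report count / mean / sample SD per (class × speaker)
  cell; the Total row pools speakers by count-weighted mean.  The Total
  SD is the SD of the pooled sample (the alternative — a pooled-variance
  formula — is not used; only Total means are treated as exact).
* Brown–Forsythe: one-way ANOVA F on |x − group median| with
  (k−1, N−k) df, implemented directly and cross-checked in tests
  against an independent two-step oracle and scipy's median-centered
  Levene.  Speakers are pooled by default.
* CV equality: likelihood-ratio test for a common coefficient of
  variation under normal models, with the group means profiled out
  through a closed-form quadratic root and the common CV optimised
  numerically.  For two groups the signed likelihood root is adjusted
  by a Barndorff-Nielsen-type modification `r* = r − log(r/q)/r` with a
  Wald-type `q` from the delta-method CV variance
  `cv²(½ + cv²)/n`; p-values are two-sided normal.  The source prints
  no worked statistic for this test, so its acceptance surface is
  calibration: the test suite verifies type-I error within
  0.035–0.065 at α = 0.05 over 2,000 simulations (n = 80 per group)
  and power above 0.8 against a threefold CV difference over 500
  simulations.  Groups with |CV| > 10 (mean near zero) are rejected
  as unstable.
* Mixed models are delegated to statsmodels MixedLM (random intercept
  per speaker, joint Wald chi-square for the class factor) as an
  interface contract — restricted-likelihood internals, conservative
  df methods and post-hoc contrasts are out of scope.
* α = 0.05 throughout; no multiple-testing correction is applied.

## Validation problem sizes

The validation battery (also run by `scripts/acceptance.py`) uses:
noiseless 149-frame phantoms for the tracker-vs-oracle and distractor
checks; a 20-point grid (4 amplitudes × 5 onset lags) for end-to-end
recovery; 2,000 two-group simulations (n = 80) for variance-test
calibration; and 200 replicate studies at the published pooled SDs and
counts for the variance-ordering check.  These sizes give Monte-Carlo
error comfortably below the decision margins they feed.

## Known limitations

* ROI placement and VTR/seed selection come from configuration or
  phantom truth; no interactive or anatomical placement is provided.
* The tracker is validated on the larynx use case only; velum tracking
  would use the same machinery but is untested against anatomy.
* The simulator's normal, independent-measure model reproduces printed
  group means/SDs and counts, not higher moments or within-speaker
  correlation structure.
* Landmark detection assumes a single gesture per analysis window;
  signals with multiple movement cycles need windowing upstream.
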