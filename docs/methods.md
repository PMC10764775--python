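# Methods

`bitekin` analyses the feeding strike of a benthic-biting fish from 2D
landmark time series digitized from lateral-view high-speed video. This
note documents the model the pipeline implements, the synthetic data it
is validated against, the tunable parameters, and the numerical choices
made where the design was genuinely open.

## The kinematic model

A bite is described by landmark-derived time series sampled at a uniform
step (default 5 ms, i.e. 1000 fps video landmarked every 5 frames):

- **Gape** — distance between the upper (C) and lower (F) jaw-tip
  landmarks, `d_t = sqrt((x_C - x_F)^2 + (y_C - y_F)^2)`.
- **Per-step displacement** of one landmark,
  `d = sqrt((x_t - x_{t-1})^2 + (y_t - y_{t-1})^2)`.
- **Three-point angles** evaluated at a vertex landmark by the arccos of
  the normalized dot product of the two arm vectors, clamped to [-1, 1]
  before the arccos. Reported in degrees, always in [0, 180]. The
  tracked angles are: cranial (A–K–L, neurocranium tip / craniovertebral
  fulcrum / dorsal body reference), intramandibular (F–P–E), pelvic
  (I–K–A), girdle (A–K–J), and the two ventral out-lever angles E–K–I
  and I–K–O.
- **Cranial elevation** is reported as the *decrease* of the cranial
  angle from its value at t0: elevating the neurocranium swings its
  anterior tip toward the dorsal body reference, so the raw angle
  shrinks. This sign convention makes the elevation trace rise during
  ventral expansion and fall during the ventral pull, for any upright
  lateral-view digitization.
- **Benthos distance** — the substrate is the line `ax + by + c = 0`
  (normalized, `a^2 + b^2 = 1`) through the time-averaged benthos
  landmarks; perpendicular distance is
  `|a x + b y + c| / sqrt(a^2 + b^2)`. Benthos landmarks must be static;
  the check uses RMS (not max) deviation so observation noise alone
  cannot trip it.
- **t = 0** is the first frame in which the opened jaws begin to close:
  the first local maximum of the smoothed gape exceeding 20% of the
  overall maximum and followed by 3 strictly decreasing samples.

Coordinates are converted from pixels with a single ruler-derived scale
(`mm_per_pixel`); a second calibration of an already-calibrated set is
an error. Input tables in image convention (y down) are flipped to y-up
on read. Missing landmarks are allowed only as a terminal suffix
(digitization stops when the fish leaves lateral view) and truncate the
sequence; interior gaps are fatal and nothing is interpolated.

## Phase segmentation

A complete bite is cut into five contiguous phases by five boundaries:

| cut | definition |
|-----|------------|
| t0  | gape-closure onset (above) |
| c1  | end of phase 1: start of the ventral-expansion rise, or first-cycle closure when no expansion occurs |
| c2  | ventral-pull onset: the cranial-elevation argmax between the gape cycles, at the first sustained (two-step) decline of at least `delta_pull` per step |
| c3  | extremum of intramandibular (IMJ) flexion relative to first closure |
| c4  | second-cycle opening onset |
| end | second-cycle closure |

Gape cycles are runs of at least 3 samples above a closed-gape
threshold. The threshold is the 5th-percentile baseline plus
`k_sigma = 3` times a robust noise scale estimated from the *raw*
closed-segment gape (with coincident closed jaw tips the closed gape is
folded landmark noise, so raw values, not smoothing residuals, carry the
right scale), with a 2%-of-range floor for noise-free traces. Candidate
cycles whose peak is below 20% of the largest cycle peak are discarded
as noise. Threshold crossings and the peak are located on the raw
trace — the second opening lasts only ~3 samples and smoothing would
smear it — while smoothing (Savitzky–Golay, window 5 = 25 ms, order 2)
is used for t0 and the elevation-based cuts. Opening durations
(onset→peak, the operationalization used for the reported "duration of
mouth opening") refine the peak time by a parabolic vertex through the
peak sample and its neighbours, clamped to one sample, because a
15.7 ms opening falls between 5 ms grid points.

Behaviours are scored as binary events:

- **Ventral expansion** (phase 2) is present iff the raw cumulative
  cranial-elevation rise between c1 and c2 reaches `theta_min = 1.5°`
  (inclusive, with a 0.01° numeric tolerance) while the gape stays
  closed and the jaw-tip-to-benthos distance varies by less than
  `anchor_tolerance = 0.5 mm` (the jaws stay anchored to the algae).
- **Suction** (scored separately for each cycle) is present iff the
  algae-tip landmark approaches the mouth midpoint faster than
  `v_suction = 0.2 mm/step` for two consecutive steps while closer than
  `proximity_max = 5 mm`. Without an algae-tip landmark the result is
  "unknown" (None), not false.

These thresholds are operationalizations — the behaviours they
reproduce were originally scored by eye — chosen to sit above landmark
noise (0.05 mm noise maps to ~0.15–0.2° on the tracked angles) and
below the smallest reported rotations (1.8°). `delta_pull` is 0.1°/step
rather than a larger value because the pull begins with a smooth
acceleration: the first post-peak step of a 8°/60 ms smoothstep decline
is ≈0.18°, and a larger threshold would systematically date the onset
one sample late. All thresholds are configurable via `PhaseParams`.

## The lever model

Ventral expansion is modelled as a motion input–output system about the
craniovertebral fulcrum K. The input is cranial rotation θ1 (the change
of angle A–K–L over the phase-2 interval); a point at radius r from K
rotating by θ travels the chord `2 r sin(θ/2)`, so the predicted motion
of the dorsal reference L is `2·KL·sin(θ1/2)`. The output is the
expansion of the ventral margin, measured as ΔEI + ΔIO. Each term is
predicted by the law of cosines on its own sub-triangle: with measured
levers KE, KI (and KI, KO), start angle θ and observed angle change Δθ,
`EI(θ) = sqrt(KE² + KI² − 2·KE·KI·cos θ)` evaluated at θ and θ + Δθ.

The decomposition into sub-triangles E–K–I and I–K–O (rather than a
single E–K–O triangle with an arbitrary split of the combined angle) is
exact for rigid planar rotation about K and uses only angles the videos
provide. Exactness on rigid geometry is the module's master oracle: on
noise-free synthetic bites the predicted and observed input and output
motion agree to better than 1e-9 mm (regression slope 1, intercept 0).
Both angle components and their sum are reported. Levers are measured
per specimen as the median over frames of the distance from K; a
within-bite coefficient of variation above 0.05 flags (but does not
reject) a lever, since the segments are assumed quasi-rigid. Start
angles are taken at the first frame of phase 2 and changes over the
whole interval, one observation per bite. Agreement across bites is
quantified by OLS (Gaussian GLM) of observed on predicted motion.
Scaling all levers by a factor s scales every predicted displacement by
s — the geometric reason deeper-bodied fish gain more ventral motion
per degree of cranial rotation.

## Statistics

- **Binomial GLM**: logistic regression of event presence on algal
  length, fitted by iteratively reweighted least squares on a
  standardized predictor (convergence: relative deviance change < 1e-8
  or 25 iterations; separation declared when any standardized
  coefficient exceeds 50). Wald z and p per coefficient. The quantity
  of interest is the odds = 0.5 crossing `x* = −β0/β1`, the algal
  length at which the fitted probability equals one half. A
  `statsmodels` binomial GLM serves as an independent cross-check in
  the tests (agreement to 1e-6), never as the implementation.
- **Gaussian GLM**: ordinary least squares, shared with the lever-model
  agreement test (slope, intercept, t, p, R²).
- **Unequal-variance comparison** of first vs second jaw-opening
  durations: Welch's statistic with Satterthwaite degrees of freedom,
  the two-sample inference equivalent of a GLS fit giving each factor
  level its own variance; a Brown–Forsythe (median-centred Levene) test
  of variance homogeneity is reported alongside, as are both group
  variances. Under the null its rejection rate at α = 0.05 is within
  [0.03, 0.07] over 2000 simulations (calibration property).
- **Summaries** are mean ± standard error (sd/√n). No multiple-testing
  correction is applied; p-values are reported unadjusted.

Bites are pooled across individuals; no individual-level random effect
is fitted (the study pools 8 + 10 + 5 bites from three fish). Adding
one is a possible extension, not a default.

## The synthetic-bite generator

The generator is the pipeline's ground-truthed test substrate: a planar
articulated linkage with fulcrum K at 15 mm above a horizontal benthos,
a rigid neurocranium carrying the anterior tip A, jaw joint E and the
jaw assembly (E → IMJ point P → lower tip F; the upper tip C is F
reflected about the jaw midline, so gape maps exactly to the opening
angle), post-cranial points L, J, I, O at fixed radii from K, a
pectoral fin (G, H, M), two static benthos landmarks and an optional
algae tip — 15 body/benthos landmarks plus the optional tip. Segment
proportions are plausible for an ~84 mm standard-length grazer and are
config-overridable; they are not measured anatomy.

The default schedule *is* the study condition set: first opening
120 ms; closure 80 ms with 5.3° cranial elevation and 1.8° pelvic
rotation; ventral expansion 19.6 ms with 4.2° cranial elevation and
1.8° girdle and pelvic angle increases (jaw tips pinned by
construction — the anchor is enforced, not emergent); ventral pull
60 ms with 8° ventral head rotation and IMJ flexion up to 93°; an
81.5 ms head-flick interval (lateral motion is out of plane and not
simulated; the IMJ returns to rest here so its extremum dates the end
of the pull); and a second gape cycle of 15.7 ms opening + 40 ms
closing with a suction burst. These durations total 416.8 ms of bite.
The closing (80 ms), pull (60 ms), flick (81.5 ms) and second-closing
(40 ms) durations are not individually constrained by the reported
means; they were chosen once so the full sequence matches the reported
total duration, and are configurable. Amplitude parameters are defined
as the changes in the *measured* angles over each phase, which is what
the analysis recovers.

Rotations follow cubic smoothstep ramps, so angular-change traces are
continuous and peak mid-phase. Gape ramps are truncated quarter-sine
profiles with non-zero velocity at the opening onset, at peak gape and
at the return to closed: jaw openings start and stop abruptly in real
strikes, and a ramp that is differentiable-flat at its ends would make
the closure onset (t0) unlocalizable at 5 ms sampling under noise. The
algae tip sits on the benthos until first closure, is then gripped
1.8 mm beyond the jaw tips (the digitized tip is the free end of the
strand) and follows the jaws through the pull; when the jaws reopen it
is released and drawn in only by the (optional) suction displacement.

Observation noise is iid Gaussian per landmark per frame (default σ for
noisy fixtures: 0.05 mm, about the precision of careful manual
digitization at these magnifications). Rigid segments are exactly rigid
before noise; all randomness flows from a single seed, and identical
configs produce bit-identical tables.

**What passing tests show, and what they do not.** The generator
reproduces the statistical and geometric structure the analysis
assumes: rigid levers, planar motion, static benthos, smooth
single-peaked phase ramps, logistic behaviour probabilities. Real
digitized bites add out-of-plane motion, correlated digitization error,
body flexion between the "rigid" points, and irregular multi-peaked
gape traces. Parameter recovery on synthetic bites therefore validates
the *implementation* of the estimators and detectors, not their
robustness to every artefact of real video.

## Numerical choices and degenerate inputs

- Angles: arccos of clamped normalized dot product; zero-length arms
  raise an error naming the frame. Near 0°/180° the conditioning of
  arccos limits agreement with the law-of-cosines form to ~1e-5°.
- Coordinates are stored to 6 decimals; write→read round trips are
  bit-identical at that precision.
- Boundary errors in recovery tests are measured against the
  grid-quantized true boundary (the schedule is continuous in time;
  the sampled data cannot resolve below one 5 ms step).
- Problem sizes: recovery tests use 20–50 simulated bites (~90 frames
  each), the logistic coverage property 100 fits at n = 500, the Welch
  calibration 2000 vectorized null simulations. The full suite runs in
  a few seconds on one core.
- A bite with no gape cycle is "not a bite" (error); a single-cycle
  bite yields a partial segmentation (phases 1–3) with a warning;
  per-bite failures in the directory pipeline are logged and skipped,
  and the run fails only if every bite fails.

## Known limitations

- Phase 4 (lateral head flick) is an interval and flag only; its
  amplitude is out of plane for 2D landmarks.
- The ventral-pull onset rule (elevation argmax + sustained decline) is
  an operationalization; the source behaviour had no published trace
  criterion. Detected phase-2 durations carry a ~+2–4 ms bias from the
  smooth onset of the pull.
- The suction detector needs the algae-tip landmark; without it the
  flag is unknown rather than inferred from jaw kinematics.
- Lever-model observations use detected phase boundaries; a boundary
  that slips one sample into phase 3 mixes a little pull motion into
  the input measurement (the exactness oracle therefore uses exact
  intervals).
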