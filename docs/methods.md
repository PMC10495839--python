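# Methods

This note documents the models behind `capstall`, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout.

## Stall definition and the correlation statistic

A capillary stall is operationally defined as the same RBC shadows being
stationary for **at least two consecutive frames**. At a 0.57 Hz volume rate
(frame period 1/0.57 ≈ 1.754 s) and mm/s RBC speeds, a flowing capillary
presents an essentially independent shadow arrangement every frame, so the
Pearson correlation between consecutive rows of the length–time (LT) image
is near zero during flow and rises sharply during a stall.

The detector thresholds r(t) (default **0.4**) and marks *both* frames of a
suprathreshold pair as stalled: a correlation is a property of a frame pair,
and this mapping makes the minimum detectable event exactly two frames — one
frame interval, 1.75 s. The threshold is deliberately low; the intended
operating point favors sensitivity, with false positives meant to be cheap
to reject (against ground truth in simulation, by manual review on real
data). A data-driven alternative (per-capillary mean + 2 SD of the trace)
is available behind `adaptive_threshold`.

Zero-variance LT rows contribute r = 0 with a degeneracy flag: a featureless
row carries no evidence of a frozen shadow pattern.

### LT preprocessing

Two artifacts of practical centerlines shape the statistic:

* A pixel-skeleton centerline runs slightly off the true vessel axis, so a
  **static** brightness pattern rides on every LT row and correlates all
  frame pairs regardless of flow. The pipeline therefore subtracts each
  column's temporal mean before correlating (`lt_detrend`, default on). A
  frozen shadow pattern still deviates identically from the column mean in
  consecutive rows, so stall evidence survives.
* Optional utilities exist for along-length Gaussian smoothing
  (`smooth_lt`) and thin transverse band averaging (`extract_lt_band`).
  Both raise the per-pair stall correlation, but they also reduce the
  effective number of independent samples per row and thereby *widen* the
  flow-state correlation distribution; measured end to end, they produce
  more false positives at the default threshold than they recover misses,
  so both default off.

## Stallogram statistics

With `S` the capillaries × frames boolean stallogram, `n` counted
capillaries and `T` frames:

* **incidence** = 100 · (#rows with ≥ 1 true) / n;
* **point prevalence** = 100 · mean over frames of (column sum / n);
* **cumulative stall duration** = 100 · mean over *stalling* rows of
  (row sum / T). Units are percent of record duration per stalling
  capillary; the identity `prevalence · n · T = Σ S` holds exactly before
  percentage scaling.

Duration filtering removes events shorter than `min_frames` (≥ 2; 2 keeps
every stall, since no detected event is shorter). At the default frame
period, `min_frames = 5` keeps only stalls of ≈ 8.8 s or longer — the
regime visible to slower angiography — which is how high-rate and low-rate
measurements are compared.

The growth of incidence with measurement time is summarized by
`I(t) = A(1 − exp(−B t)) + C` with `t` in minutes: a subset of capillaries
stalls repeatedly, so the pool of observed stallers saturates. The fit is
nonlinear least squares (`scipy.optimize.least_squares`, B bounded
positive, tolerances 1e-15) with a three-point multi-start — the caller's
initial guess plus two data-driven guesses — taking the converged solution
with the lowest residual. A constant curve is reported as A = 0,
C = mean, with B flagged unidentifiable. Noiseless curves generated from
the model are recovered to ≤ 1e-6 relative error from the distant start
(1, 1, 0).

## Centerline extraction

The extraction image is the **temporal mean** of the stack: shadows average
out, maximizing lumen contrast. Frangi vesselness (scales {1, 2, 3, 4} px,
covering roughly 1.4–5.6 µm radii at 1.393 µm/px) is thresholded by Otsu's
method by default (a manual threshold is accepted), thinned to a one-pixel
skeleton, and converted to a graph: skeleton pixels with ≠ 2 neighbors are
nodes (endpoints, branchpoints), maximal degree-2 paths between them are
edges, and an isolated cycle is anchored at its lexicographically smallest
pixel as a closed self-edge. A click selects the edge containing the
closest path pixel (ties go to the lowest edge id; nothing within
`max_click_distance_px` = 20 px is an error). Centerlines of 5 px or less
are excluded from analysis.

## Registration and LT extraction

Each capillary's crop (bounding box + 10 px margin) is registered by
normalized cross-correlation against the temporal-mean crop, translation
only — head-fixed preparations drift rigidly at this scale. Because a mean
built from moving frames is blurred (its correlation maximum is pulled
toward the offset centroid), integer alignment and reference rebuilding are
iterated to a fixed point before one subpixel pass (quadratic interpolation
of the correlation peak along each axis). Per-frame estimates jitter
because moving shadows perturb the along-vessel peak, while true drift is
slow, so offset traces are median-filtered over 5 frames (a median
preserves constant offsets and clean steps exactly). Circularly shifted
test stacks are recovered exactly at integer lags and to < 0.25 px at half
integer lags.

LT values are bilinear samples of each frame at the shifted centerline
points; out-of-bounds samples take the nearest-edge value and are counted.

## Vessel dynamics

Diameter is the FWHM of an averaged cross-vessel profile: 20 lines spaced
2 µm along the axis, sampled perpendicular to it at 0.5 µm steps, averaged,
min–max normalized; the diameter is the distance between the two half-max
crossings, each linearly interpolated between samples. The estimator is
exact to < 1% on noiseless soft-edged rectangles and Gaussians at any
sub-pixel placement, and line averaging demonstrably reduces its variance
under noise. A profile that never falls below half maximum on one side
raises an error (NaN with a flag in the per-frame trace).

ΔF/F uses the ROI-mean intensity with baseline F0 = 10th percentile of the
trace — robust to dilation transients; the common alternative of a
quiescent-period mean requires a human choice the pipeline avoids.

"Large" dilations are local maxima of the fractional diameter increase over
a rolling-median baseline (width 31 frames, tolerant of slow drift)
reaching ≥ 10% (configurable); any qualifying peak with another qualifying
peak within ±10 frames (±17.5 s) is excluded — both drop — so triggered
averages are not confounded by overlapping events. The triggered average
aligns windows at peak diameter (lag 0), reports the mean across events and
the SEM across events, and drops (and logs) events whose window leaves the
record.

## The synthetic-data generator

The simulator emulates the phenomenology the detector relies on, with exact
ground truth:

* **Geometry** — capillaries are quasi-parallel smooth lanes (one shared
  near-axis direction, stratified lane offsets, small sinusoidal wiggle)
  with a guaranteed minimum separation of 3 capillary widths. Real
  capillary networks branch and cross; parallel lanes are a deliberate
  idealization that keeps centerline tests unconfounded by crossings, and
  it is the reason the field can hold 50 capillaries of 180–260 px at the
  required separation. Lengths (180–260 px ≈ 250–360 µm) are chosen so LT
  rows carry enough independent shadow structure for the frame-pair
  correlation to be well conditioned; they represent long projected paths
  through the imaged volume.
* **Shadows** — 1D dark Gaussian dips (σ = 3 µm ≈ RBC radius, depth 0.6)
  at Poisson positions along the centerline (default 5 per 100 µm),
  rendered through the capillary's Gaussian tube profile (lumen FWHM
  4 µm). Flowing frames redraw positions independently — at mm/s speeds
  shadows traverse many capillary lengths per 1.75 s frame, so no frame-to-
  frame advection survives; stalled frames reuse the frozen positions
  exactly (only noise varies).
* **Stall process** — per capillary, a two-state renewal process:
  exponential waiting time to onset (default 0.4/min), stall durations
  geometric with minimum 2 frames (p = 0.35, mean ≈ 3.9 frames ≈ 6.8 s —
  most stalls short, as high-rate imaging shows), one flowing frame of
  refractory time so events and stallogram runs stay in bijection. Half
  the capillaries are eligible to stall (`stalling_fraction` = 0.5): with
  ~4 expected onsets per eligible capillary in 10 min this yields ~50%
  incidence and ~2% point prevalence — higher than typical in-vivo numbers,
  chosen so that sensitivity and incidence estimates on 30–50 capillaries
  carry useful statistical power.
* **Noise and motion** — additive Gaussian intensity noise (SD 0.25 of
  lumen brightness, placing stall-pair correlations near 0.6 and flow
  pairs near 0 ± 0.12, the regime real correlation traces display),
  clipped at zero; smooth rigid drift up to `motion_amplitude` (1 px).
* **Arteriole** — an erf-edged vertical band whose width *is* the diameter
  trace (baseline + Gaussian-in-time dilation bumps) and whose brightness
  is modulated by 1 + ΔF/F with ΔF/F = coupling_gain × fractional diameter
  change + noise.

Not emulated: optical PSF and depth effects, photobleaching, shot-noise
statistics (noise is Gaussian, not Poisson), vessel branching/crossing,
non-rigid motion, flow-speed variation (all flowing frames decorrelate
completely). Consequently, passing tests demonstrate the pipeline's
correctness under the stated model — frozen-vs-redrawn shadows with rigid
drift — not its performance on real angiograms, where static structure,
partial decorrelation of slow flow, and crossing vessels make the detector's
specificity much worse (which is why its output is a candidate list for
review, not a final answer).

## Numerical conventions and edge cases

* Coordinates are 0-based (x = column, y = row) in every API and CSV.
* All randomness flows from a single `numpy` Generator per simulation;
  identical (config, seed) reproduce outputs bit for bit.
* TIFF stacks are written float32 with embedded frame-period/pixel-size
  metadata (bit-exact round trips); 16-bit quantized export is optional.
* Degenerate cases are conventions, not errors, where evidence is merely
  absent (zero-variance rows → r = 0 + flag; no stalling capillary →
  cumulative duration 0 + flag) and errors where the request is malformed
  (single-frame stall intervals, empty scale lists, out-of-range events,
  clicks far from any vessel, unbracketed FWHM, zero F0).

## Problem sizes

The test suite runs the full pipeline at the native frame size (512×512,
350 frames) with 30 capillaries for the detector-sensitivity check and 50
for the end-to-end validation; unit tests use smaller fields (128–256 px,
40–200 frames) chosen to keep the whole suite around two minutes on one
CPU while still exercising every code path at realistic geometry.
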