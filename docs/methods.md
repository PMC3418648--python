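# Methods

## Overview

`imbiomark` estimates arterial wall stiffness non-invasively from
ultrasound time sequences.  The measurement principle: over one cardiac
cycle the pressure pulse strains the vessel wall; at a given pulse
pressure, a stiffer wall strains less.  The pipeline therefore tracks
tissue motion between consecutive frames inside small measurement
windows, assembles the axial strain component into elastograms of the
wall, reduces them to a mean-axial-strain (MAS) time series over a
region of interest, and summarises the cardiac cycles of that series
into scalar biomarkers that can be compared across groups.

Two protocols are supported:

* **High-frequency RF (rodent carotid).**  Radio-frequency data keep
  the echo phase, so subsample axial motion is measurable.  Strain is
  measured in the near wall only (echo attenuation with depth makes the
  far wall unreliable at 40 MHz), and the biomarkers are the peak
  systolic and peak diastolic strain (PSS, PDS), each averaged over
  three cardiac cycles.
* **B-mode (human ascending aorta).**  Envelope video from a cardiac
  probe.  Bulk cardiac/respiratory motion is first removed by rigid
  registration; both walls are usable, and the biomarkers are the mean
  systolic and mean diastolic strain (MSS, MDS) with the reported
  scalar (|MSS| + |MDS|)/2.

Sign convention throughout: **compression positive**.  Systolic wall
thinning reads positive, diastolic dilation negative.  The raw
engineering strain from the tracker has the opposite sign and is
negated when elastograms are assembled.

## Affine window tracking

Within a measurement window the motion between frames t and t + δt is
modelled as affine: a point (x, y) maps to

    x' = x + T1 + Δxx (x − xc) + Δxy (y − yc)
    y' = y + T2 + Δyx (x − xc) + Δyy (y − yc)

about the window centre (xc, yc).  T1/T2 are the lateral/axial
translations, Δyy the axial strain (the reported quantity), Δxx the
lateral strain, Δxy/Δyx shears.  Estimation is two-stage:

1. **Translation** by zero-normalised cross-correlation over a bounded
   lag search (overlap-normalised sliding sums, so partial overlaps are
   normalised correctly), refined to subsample precision by a parabolic
   fit of the correlation peak in each axis.  A peak on the search
   boundary is flagged non-converged; an exact peak (NCC = 1, an
   integer-lag perfect match) skips the parabolic step, which would
   otherwise bias it.
2. **Deformation** by damped (Levenberg-style) iterative least squares
   on the sum of squared differences between the window at t and the
   warped window at t + δt, over all six parameters jointly, starting
   from the translation estimate and zero deformation.  Warping uses
   quintic B-spline interpolation: at the RF carrier frequency
   (40 MHz / 500 MHz = 0.08 cycles per sample) cubic interpolation
   error is large enough to bias Δyy at the few-1e-4 level, which
   matters for sub-percent strains; quintic makes it negligible.
   Deformation entries are bounded to ±0.2 (decorrelated speckle can
   otherwise drive the fit to divergence), the iteration stops when the
   parameter update falls below 1e-6 (max 50 iterations), and windows
   that cannot improve the fit report `converged=False` rather than
   raising.

Window geometry follows the high-frequency protocol: 108 µm axial ×
312 µm lateral (70 × 10 samples at 1.54 µm axial spacing and 30 µm line
pitch), 90 % overlap in both axes, i.e. steps of 7 samples axially and
1 line laterally.  The axial/lateral assignment of the 108 × 312 µm
window is an open choice (the protocol source does not state it); it is
configurable.  Only consecutive-frame pairs are tracked; δt is fixed at
one frame interval.

## Elastograms

Per frame pair, the Δyy of every window is placed on the overlapping
window grid (counts follow floor((extent − window)/step) + 1 per axis).
Windows whose centre lies outside the selected wall band of the
segmentation mask are missing; so are unconverged windows and windows
touching NaN-flagged (out-of-view) samples.  Elastograms are
post-filtered with a 5 × 5 median on the *window grid* (the elastogram's
own pixels, not RF samples).  The median ignores missing neighbours;
edge cells see a reflect-padded block, which keeps the filter idempotent
on piecewise-constant fields (a truncated even-count block would
interpolate a tie and invent values neither region contains).  Display
rendering overlays the strain map on the B-mode with a diverging scale,
positive (compressive) strain in the blue half.

## Rigid registration (B-mode)

Each frame is aligned to a fixed reference (the first frame by default)
with two translations and one in-plane rotation about the image centre,
maximising NCC.  The search is exhaustive over a coarse grid (1 sample,
0.5°), followed by a fine angular pass at 0.1° around the best angle —
the per-angle score (best over integer shifts) is too jagged for a
parabolic fit on the coarse grid alone — and parabolic refinement of
shift and angle.  Frames are resampled bilinearly; samples pulled from
outside the field of view become NaN and are excluded from downstream
windows.  Whether to register to a fixed frame or cumulatively
frame-to-frame is an open protocol question; fixed-reference was chosen
for determinism and because it cannot accumulate drift.

## MAS curve and biomarkers

The MAS curve is the mean of the non-missing elastogram values inside a
fixed ROI (default 5 × 9 window-grid cells for the rodent near wall,
3 × 9 for the ascending aorta), per frame pair, in percent.  By default
the ROI centres on the cell with the largest time-mean strain magnitude
(the protocol places it "within the wall" without coordinates); explicit
placement is supported.

Cycle detection: with an ECG channel, cycles are gated by R-peaks.
Otherwise the period comes from the biased autocorrelation of the curve
(the biased estimate decays with lag, so its global peak is the
fundamental, not a late harmonic).  Systolic peaks and diastolic troughs
are local extrema subject to a minimum spacing of 0.8 period and a
sign-vs-mean constraint; no prominence threshold is applied because
cycles truncated by the ends of the recording have arbitrarily small
prominence (a 7-cycle recording must yield 7 peaks and 7 troughs).

Biomarkers average the three most central cycles (which three of the
~7 recorded cycles enter the average is unstated in the protocol;
central cycles avoid the truncated edges; configurable):

* peak mode: PSS = mean of the systolic peak values, PDS = mean
  magnitude of the diastolic troughs;
* mean mode: per cycle, MSS is the mean of the positive-strain samples
  and MDS the mean of the negative-strain samples (positive = systolic
  under the sign convention); the reported scalar is
  (|MSS| + |MDS|)/2, robust to a systole/diastole offset.  No
  detrending is applied.

Pooling: the rodent scheme pools sides (left/right) and cycle phases
(systole/diastole), 4 observations per animal; the human scheme pools
near/far walls and triplicate recordings, 6 per subject.  The
multiplier is the product of the pooled factor level counts.

## Group statistics

One-way designs: classical ANOVA and Kruskal–Wallis, Tukey HSD for all
pairwise contrasts, and Dunnett's many-to-one test against a baseline
group.  Dunnett p-values and critical values are estimated by seeded
Monte-Carlo simulation of the null max-|t| distribution (group means
sharing the baseline and a pooled χ² variance draw; 100 000 draws by
default).  This handles arbitrary group counts and unbalanced sizes and
reproduces the multivariate-t reference implementation to |Δp| < 0.01.
The turning point of an age-ordered series is the earliest age whose
Dunnett-adjusted contrast with the youngest group is significant at
α = 0.05; with no significant age it is None.  When every group has
zero within-group variance the parametric tests are degenerate; a
warning is recorded and only the rank test runs.

## Synthetic phantom

The phantom renders a longitudinal vessel view: echogenic near/far wall
bands around a hypoechoic lumen in an anechoic margin.  Acquisition
defaults are the high-frequency setup: 40 MHz centre frequency, 110 %
fractional bandwidth at −6 dB, 500 MHz sampling (1.54 µm axial
spacing), 60 frames/s, 8-bit export.  Phantom defaults: 150 µm walls,
800 µm lumen, 150 µm margins, 32 lines at 30 µm pitch (960 µm wide),
2000 scatterers/mm² (several per resolution cell — fully developed
speckle), wall-to-lumen echogenicity 10, heart rate 351 beats/min,
7 cycles, peak inter-frame strain 2 %, additive white noise at 0.1 of
the signal RMS.  Values beyond the acquisition constants are not fixed
by any protocol; they were chosen once as a realistic rat common
carotid at this magnification and are configurable.

Kinematics: wall through-thickness compression follows a raised-cosine
in cardiac phase, anchored at each wall's outer boundary; the lumen
halves ride rigidly on their wall's inner boundary (walls thin while
the lumen dilates, as in systole).  The cumulative amplitude is solved
numerically so that the peak inter-frame engineering strain over the
actual frame grid equals the configured peak exactly.  Exported ground
truth is the engineering compression between consecutive frames,
(c_{k+1} − c_k)/(1 − c_k) — exactly what an ideal tracker measures, and
exactly consistent (to 1e-6) with finite differences of the analytic
scatterer displacement field.

Rendering: each scatterer contributes a separable PSF — a
Gaussian-windowed cosine at the carrier axially (envelope width from
the fractional bandwidth) and a Gaussian laterally (default 80 µm at
−6 dB).  White Gaussian noise is added pre-envelope with a standard
deviation fixed from the rest-state frame, so noise is stationary over
the sequence.  Optional depth attenuation (dB/mm) emulates the
near/far-wall SNR asymmetry.  B-mode frames are the analytic-signal
envelope log-compressed over 40 dB, normalised sequence-wide.

What the phantom does *not* emulate: wave propagation (no diffraction,
reverberation or phase aberration), out-of-plane motion and speckle
decorrelation, blood flow signal, probe sway, tissue anisotropy, or
manual per-elastogram segmentation (masks follow the analytic
boundaries).  Passing the end-to-end tests therefore demonstrates that
the estimator chain is unbiased and self-consistent under its own
motion model at realistic speckle statistics and SNR — not that it is
robust to every artefact of in vivo recordings.

## Problem sizes and numerical choices

The shipped validation runs at desk scale, chosen so the whole suite
and the acceptance script each finish in minutes on one CPU: a 72-frame
phantom (7 cycles at 351 beats/min), 910 × 32 samples per frame,
~300 near-wall windows per frame pair; 50 windows for the
estimator-vs-grid-search check (grid step 1e-4 over ±5 %); 200
replicates for the turning-point and group-discrimination simulations
(Dunnett draws reduced to 20 000 there; 100 000 elsewhere).  End-to-end
PSS recovery on the phantom is accurate to a few percent relative —
dominated by windows straddling the wall/lumen boundary — against a
15 % acceptance band.

Degenerate inputs: constant patches raise `DegenerateInputError`
(cross-correlation is undefined); constant MAS curves raise
`CycleDetectionError` advising a manual period; an all-background mask
yields an entirely missing elastogram rather than an error.  All
randomness is driven by explicit seeds; identical configurations and
seeds give bit-identical phantoms and Monte-Carlo results.
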