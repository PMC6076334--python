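# Methods

This note records the models the toolkit implements, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would want to know.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Physical conventions

Frames are 33 ms apart (`frame_interval = 0.033 s`); the default camera
calibration is 0.1 µm/pixel.  Trajectory positions are stored in pixels by
the tracking layer and converted to micrometres at the statistics boundary,
so a different camera is a single config change.  Pixel coordinates are
0-based with pixel centers at integers; a spot position is a continuous
(x, y).

## Synthetic data

**Trajectories.**  2-D random walks with per-axis step variance `2 D δt`
(so the mean squared planar step is `4 D δt`).  A static mixture of states
assigns each track one `(D, C_n)` state for its whole life; optional
Markov switching (a per-frame redraw probability) exists behind a flag and
is not used by any test.  Confinement is a reflecting square of side `C`,
implemented by mirror-folding; its stationary ensemble MSD plateau is
`C²/3` exactly (twice the per-axis uniform variance, two axes), which the
test suite checks against a 30 000-track ensemble.

**Movies.**  Each emitter is a symmetric Gaussian of width
`psf_sigma = 2 px`.  A track's amplitude is drawn once from
`Normal(n·µ, n·σ²)` for oligomer size `n` (defaults µ = 1000, σ = 200
a.u.), on a planar background `a·x + b·y + offset`.  Noise defaults to
Poisson shot noise plus additive Gaussian read noise (SD 10 a.u.) —
EMCCD-like without modeling the gain register.  Emitters leaving the field
are clipped from the rendering but stay in the ground truth.

**Focus stacks.**  Bright-field iris images blur with defocus:
`blur_sigma(dz) = 0.6 + 2.5·|dz| px`, capped at 25 px.  The slope is a
generator design constant: it makes one 32-nm fine step change the blur
measurably through the sharpness score, while the ±4 µm in-focus slab used
for classifier labels remains a learnable boundary (blur ≈ 10.6 px at the
slab edge).  The cap encodes that far-out images stop changing.

**SRIC scenes.**  Textured ellipses (axes 8–18% of the field) on a
structured background, with the exact ellipse union as the mask.

**Dose–response tables.**  Per-cell MSD(66 ms) values are drawn as
`MSD·exp(σZ − σ²/2)` around the model curve, so each condition's *mean*
equals the curve (the same −σ²/2 median convention the log-normal
likelihood uses) and σ = 0 reproduces the curve exactly.

What the generators do **not** emulate: vectorial/astigmatic PSFs, the
evanescent-field depth of TIRF illumination, photobleaching and blinking,
EM-gain noise statistics, cell morphology beyond ellipses, and spatial
heterogeneity of diffusion within a cell.  Passing recovery tests
therefore demonstrate estimator correctness under the stated models, not
robustness to those real-data effects.

## Neural network

Three stride-2 3×3 convolutions (8/16/32 channels), three mirrored
transposed convolutions, ReLU activations, sigmoid output; He
initialization; mean-squared-error loss (consistent with the ARS used for
evaluation; binary cross-entropy behind a flag); Adam with β = (0.9,
0.999), lr = 1e-3.  Channel widths, kernel sizes and optimizer settings
are our own smallest-net-that-works choices; the fixed structure (3+3,
ReLU hidden, sigmoid final) is the part that matters.  Input sizes must be
divisible by 8; the ARS normalizer generalizes from the 512² grid to the
actual pixel count.  All of it is numpy (im2col convolutions, manual
backprop) so training runs in seconds on one CPU at the 32–64 px sizes the
tests use; weights and architecture serialize to one `.npz` settings file.

Normalization differs by task on purpose: the focus classifier
standardizes each image (blur, not brightness, is the cue), while the
cell-search nets use a median-offset, *fixed-gain* normalization
calibrated on the training pool — absolute brightness is exactly what
separates a suitable spot density from an over-expressing cell, and
per-image standardization would erase it.

## Autofocus

Coarse: scan 750 µm in 2.5 µm steps, ascending; at each position the
classifier's mean output map is the evaluation value; the first value
above 0.5 stops the scan (failure status if the range is exhausted).
Training labels are 1 within 4 µm of true focus.

Fine: scan a 2200-unit window of the objective feedback system (≈ 3.5 µm)
in 20-unit (≈ 32 nm) steps.  At each position the sharpness score is
computed from the lower-half iris image: exact Otsu binarization (the
threshold is searched over every distinct value, so it equals the
exhaustive oracle by construction), 21×21 ROIs — one per 21-px column
band, the first window from the top whose white fraction is ≤ 50% —
a 512-bin histogram of the pooled ROI pixels spanning their min→max
(which makes E invariant under affine intensity rescaling), Otsu
bisection, 20-bin moving-average smoothing per side (window shrinking at
the boundaries), and `E = N(I_max1)·N(I_max2)/N(I_min)²` with the valley
taken strictly between the two peaks.  A zero valley yields a +inf
sentinel, excluded from peak fitting.  A Gaussian fit of E versus position
gives the peak; a configurable hardware offset (default 0) is added; if
the fit fails the argmax is used and flagged.

Two engineering guards wrap the single fine scan (our addition): the
window is centered on the coarse result, and (a) if the best E in the
window sits at the out-of-focus noise floor (E < 100, calibrated from the
generator's E-vs-defocus decay, where near-focus E is 10²–10⁴) the window
shifts one full range along the E trend and rescans; (b) a fitted peak on
a window edge re-centers the window there.  At most three extra scans.
Without (a), a coarse stop triggering ~6 µm early leaves the peak outside
the window and the Gaussian fit latches onto noise.

## Tracking

Detection is Pearson-normalized cross-correlation against the 11×11
Gaussian template, computed with exact spatial sums (`ndimage.correlate`
on the image and its square); borders where the window leaves the image
are invalid, constant windows get correlation 0.  Binarize at 0.25, label,
then fit each candidate with the 7-parameter Gaussian-plus-inclined-plane
model by Levenberg–Marquardt inside the 11×11 ROI; candidates closer than
5 px to the border or failing to converge are dropped and counted.

Linking enumerates all pairs closer than 6 px between consecutive frames
and accepts them greedily in ascending distance, each spot used once
(ties: previous-spot index, then current-spot index).  A Hungarian
minimum-total-distance variant exists behind `method="optimal"`; the
greedy rule is the default reading of "shortest connection", and property
tests show the two agree whenever frame-to-frame steps are well below the
spot separation.  No gap closing: a missed detection terminates the track.
Filters remove trajectories with any spot outside the cell mask or with
mean σ_A outside [1.5, 2.5] px (per-spot behind a flag).  Two-color
registration is a least-squares similarity transform (Umeyama) from
paired fiducials, ≥ 3 non-collinear points required, residual RMS
reported.

## Statistics

All estimators are maximum likelihood; every fit is validated by parameter
recovery on its own generator in the test suite.

**Confined diffusion.**  Per-cell MSD curves at lags j·δt, j = 1..15, are
fitted to `MSD(t) = (C²/3)(1 − exp(−12Dt/C²))` under two error models for
cell-to-cell scatter: normal and log-normal with the −σ²/2 mean
correction.  Per-lag scales σ_j are profiled in closed form — normal:
σ_j² is the mean squared residual; log-normal: σ_j² solves a quadratic,
`σ² = 2(√(1+mean(a²)) − 1)` with `a = log d − log MSD` — leaving a
2-parameter outer problem in (log D, log C) solved by Nelder–Mead from a
least-squares warm start plus 5 seeded random restarts.  Both models'
log-likelihoods are reported and the larger adopted.  A profiled σ is
floored at a tiny fraction of the data scale so noise-free data cannot
collapse the likelihood onto a single lag.

**Diffusion states.**  Displacements at δt = 66 ms (2 frames, overlapping
windows).  The mixture `P(r) = Σ C_n r/(2D_nδt)·exp(−r²/4D_nδt)` is an
exponential mixture in r², so EM has closed-form updates; states whose D
collapse together are merged with a warning.  Model choice is the
smallest `AIC = −2 logL + 2k` over N = 1..4 with `k = 2N − 1` (N
diffusion constants, N−1 free fractions).

**Oligomer sizes.**  First-frame spot intensities are a mixture of
`Normal(n·µ, n·σ²)` for n = 1..10 with µ, σ shared across conditions and
fractions per condition; EM with closed-form µ, σ updates, two starting
points (25th/50th intensity percentile), best log-likelihood kept.  The
mean cluster size is Σ n·C_n.

**Pharmacology.**  `MSD([L]) = MSD_max − (MSD_max−MSD_min)/(1+(EC50/[L])^h)`
with [L] = 0 pinned to MSD_max, and the noncompetitive-inhibition surface
`MSD([L],[I]) = MSD_max − (MSD_max−MSD_min)/((1+EC50/[L])(1+[I]/IC50))`.
Per-condition scales σ([L]) / σ([L],[I]) are profiled exactly as above;
the outer parameters are optimized as (log MSD_min, log ΔMSD, log EC50,
h or log IC50), which enforces MSD_max ≥ MSD_min > 0 and positive
constants.  Both error models fitted, larger log-likelihood adopted.

**Residence time** is the mean of (length−1)·δt with its standard error.
A cell's recording counts only if some spot was tracked for ≥ 1 s.
**Time courses** rebin trajectories into 40-s windows anchored at the
stimulus time and recompute state fractions, mean intensity, cluster
fractions and residence time per bin; empty bins are omitted.

## Problem sizes and determinism

Tests and the acceptance script run the estimators at the sizes the
analyses are designed for while staying desk-sized: 10⁴–10⁵ displacements
for diffusion estimators, 100 cells for the confined fit, 10⁴ spots for
cluster fractions, 18 cells × 10 concentrations and 3 cells × 6×6 grids
for pharmacology, 100 autofocus trials with one classifier training at
32×32 (coarse) / 160×80 (fine) image resolution.  Every random draw flows
from an explicit seed; identical seeds give bit-identical outputs,
including rendered TIFF stacks.

## Known limitations

The state mixture is static (no transition-rate inference); the confined
model is the square-domain approximation, not an exact first-principles
propagator; the fine-focus noise-floor threshold (E < 100) is calibrated
to this generator's iris geometry and would need re-calibration for a
different optical model; cross-validation of training-set size reports the
train/test ARS gap but no formal stopping rule; and the pipeline assumes
one movie per cell with an optional precomputed mask rather than running
cell search on the same field.
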