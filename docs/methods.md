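# Methods

This note documents the models, conventions and numerical choices
behind `flytomo`, in the spirit of a methods appendix: what is assumed,
what is configurable, and what the synthetic tests do and do not show
about real data.

## Scan geometry and bookkeeping

A continuous-rotation scan is fully described by `ScanGeometry`:
angular step Δθ (deg/frame), exposure t_exp and per-frame overhead
t_ovh (s), frame count N, start angle, detector shape, sample-plane
pixel size and objective magnification, and the dark/flat counts.
Derived per frame: θ_i = θ₀ + i·Δθ (computed multiplicatively — never
by repeated addition — so there is no floating-point drift) and
t_i = i·(t_exp + t_ovh), where t_i is the *start* of frame i's
exposure.

Angles are kept unwrapped (cumulative, e.g. 0–1080° for three turns)
because unwrapped angles preserve time order; wrapping into [0, 360°)
is a pure function applied only where periodicity matters. Projection
counts for an angular range use the fence-post convention — both
endpoint frames included, so 180° at Δθ = 0.072° holds 2501 frames and
consecutive disjoint windows share one boundary frame.

The default geometry (15 001 frames, 0.072°, 0.5 s, 0.325 µm at 10×)
is the reference full-scale acquisition. Its pure-exposure duration is
7500.5 s; real scans take slightly longer, which is why t_ovh is an
explicit free parameter (≈12 ms/frame reproduces a ~2 h 8 min wall
clock) rather than an assumed constant. The sample-plane pixel size
scales inversely with magnification at fixed detector pitch:
0.325 µm × 10 / 4 = 0.8125 µm for the 4× objective.

## Phantom

The specimen stand-in is a 2D disc (extrudable to 3D with a slow
axial contrast modulation) of "enamel" at baseline attenuation
μ_enamel (default 0.01/µm, arbitrary-but-consistent units chosen so
path integrals through the sample are O(1) and transmittance sits at a
realistic 0.2–0.6), immersed in a liquid bath at μ_liquid (0.002/µm),
inside a support circle that fits the reconstruction circle. A
deterministic quasi-periodic rod/inter-rod texture — two oblique
sinusoids, amplified and softly saturated by clipping — modulates the
enamel by ±25% at a 6 µm period. The texture is a fixed function of
the grid, so every phantom quantity is seed-free and bit-reproducible.

Dissolution enters through an exposed arc ("window") of the boundary:
after an onset time, a front advances inward at constant speed
(default 0.02 µm/s, onset 300 s), optionally faster along the rod
direction by the factor `anisotropy_gain` (cos²-weighted with boundary
angle), and voxels behind the front drop to
μ = μ_liquid + f·(μ₀ − μ_liquid) with residual fraction f (default
0.3). Validation requires μ_liquid ≤ min over the textured enamel, so
attenuation is non-increasing in time everywhere — dissolved material
never re-mineralizes. Ground truth (`demineralized_volume`) counts
voxels strictly below their t = 0 value times the voxel volume.

The constant-speed front is the simplest kinetics reproducing the
qualitative phenomenology (progressive grey-value loss, optionally
anisotropic cavity); it is *not* chemically realistic (no
reaction–diffusion, no √t diffusion limitation, no remineralization),
and the default rates are order-of-magnitude choices for a legible
desk-scale experiment, not physiological values. Alternative kinetics
can be added behind `DissolutionModel` without touching the rest of
the chain.

## Acquisition model

Each frame is rendered at the instantaneous angle of its exposure
start. At the reference geometry the sample turns 0.072° per frame —
under one detector pixel of motion at the rim — so intra-frame angular
blur is neglected by default; `blur_substeps > 1` integrates sub-angles
for stress tests. The forward projector computes parallel-beam line
integrals by sampling the field along rays `x cosθ + y sinθ = s` with
bilinear interpolation at one-pixel path steps (Riemann sum × step).
It refuses fields with support outside the inscribed circle (they
would alias under rotation) and detectors too narrow to cover the
support (truncation).

The detector response is separable and linear: multiplicative smooth
gain map (what flats measure; ±8% by default), additive dark offset
(100 counts), Poisson noise on photon counts at incident flux Φ
(default 5000 photons/pixel — rod texture clearly visible per window
but nontrivially noisy), and Gaussian read noise (σ = 2 counts) on all
frames including darks. Darks and flats (20 each) are simulated once,
at the start of the scan file, and stored inline. A per-scan seed
drives all noise; equal seeds give bit-identical stacks.

For speed, the evolving field is re-rendered only when the dissolution
front has advanced a quarter voxel since the last rendered frame —
exact for static phantoms, and at most ~0.25 voxel of front-position
error for moving ones (well under the reconstruction's own
resolution).

## Preprocessing

Dark/flat stacks are combined by pixelwise median (robust against
zingers; mean available). Transmittance is T = (P − D)/(F − D); pixels
with F ≤ D are "dead", filled from the nearest valid pixel and
recorded in a mask. The Beer–Lambert inversion clamps at ε = 10⁻⁶
(`p = −ln max(T, ε)`), making it total; the clamped-pixel count is
kept as a QC metric in the sinogram. No ring-artifact suppression is
applied by default. Sinogram rows carry each projection's unwrapped
angle and timestamp.

## Reconstruction

Filtered back-projection with explicit conventions, since the field
has no single standard:

* image pixel (i, j) sits at x = (j − (n−1)/2)·τ, y = (i − (n−1)/2)·τ
  relative to the rotation axis, with τ the detector pitch;
* the rotation axis projects to detector column (n−1)/2 +
  `center_offset_px` (a scalar config input; no auto-centering);
* filtering convolves each row with the band-limited spatial-domain
  ramp kernel (h₀ = 1/4τ², odd taps −1/π²k²τ², even taps 0) via
  zero-padded FFT — an exact linear convolution, avoiding the DC bias
  of a naive |f| multiplication — optionally apodized by
  Shepp–Logan/cosine/Hann windows in frequency;
* backprojection is linear interpolation along each row at the pixel's
  ray coordinate; rays off the detector contribute zero;
* the angular quadrature is a trapezoid rule over the closed window
  (half weights at the endpoints, which duplicate one line mod 180°),
  scaled by the number of half-turns covered, so 180°, 360° and 1080°
  windows reconstruct on the same grey scale — unnormalized attenuation
  per µm;
* rows are backprojected at their wrapped angles, which realizes
  p(θ+180°, s) = p(θ, −s) implicitly; windows may therefore start at
  any angle, and for a static object any two ≥180° windows agree to
  machine precision (measured NRMSE ~10⁻¹⁵ noise-free).

Pixels outside the inscribed circle are masked to zero. Reconstruction
is linear and deterministic, and each tomogram carries provenance
(window indices, angles, filter, offset, config hash) sufficient to
re-run it bit-identically.

## Sliding windows and time labels

`enumerate_windows(geom, n_window, stride)` lists windows
[s, s+n_window) for s = 0, stride, 2·stride, … Each carries three time
labels: t_start (first frame's exposure start — the convention used
when quoting time differences between tomograms), t_mid (central
frame; the headline nominal time, since the object evolves during the
window) and t_end. Extraction returns numpy views: overlapping windows
share frame memory, and frames keep their original angles and
timestamps.

## Analysis

Difference maps are reference-minus-current (positive = material
loss), masked to the reconstruction circle; no registration is
performed — simulated tomograms share a frame by construction, and
registering real data is a documented prerequisite, not something this
module attempts.

Segmentation thresholds the difference map. The default rule,
`otsu-final`, computes Otsu once on the final (most developed) map and
applies that single threshold to the whole series: a per-map Otsu on a
pre-onset, signal-free map would split the noise histogram and
over-segment by construction. Per-map Otsu and fixed thresholds remain
available, and the rule actually used is recorded in the result. The
largest-connected-component option is **on by default**: noise-free
recovery is essentially unbiased, but isolated noise pixels above
threshold across the much larger non-lesion area otherwise add a
systematic positive volume bias of several percent; keeping only the
contiguous lesion blob removes it.

Onset is estimated as the *start* time of the first window whose
segmented volume exceeds 3× the null band, where the null is the RMS
volume from an identical run on a static phantom segmented at the same
threshold. The start label is the principled choice: a detected cavity
proves dissolution began before the window ended, so t_start is within
one window duration of any onset that window is the first to detect;
the mid-time label would carry a built-in half-window lag.

Material dissolving *during* a window violates FBP's static-object
assumption. This is quantified, not corrected: `motion_blur_qc`
reports the NRMSE between each window reconstruction and the phantom
frozen at the window's mid-time (~6% at the desk-scale defaults,
dominated by noise and texture interpolation).

## Desk-scale experiment

Tests and the acceptance script run a scaled-down experiment with the
identical fence-post arithmetic: 3001 frames at Δθ = 0.36° — six
disjoint 501-frame/180° windows, plus an 11-window half-overlapping
set — on a 160-px detector with 0.78 µm pixels, phantom onset 300 s
and front speed 0.02 µm/s over the 1500 s scan. This size reconstructs
the whole experiment (two control runs included) in tens of seconds on
one CPU while leaving every index/angle/window relation identical in
form to the full-scale scan.

## What the synthetic tests do and do not show

The generator shares the real experiment's *structure* — fly-scan
frame ordering, darks/flats at scan start, flat-field inhomogeneity,
Poisson statistics, a monotonically growing low-attenuation lesion
behind an exposed window — so it exercises the bookkeeping,
normalization, reconstruction and time-series chain end to end against
exact ground truth. It does not emulate: polychromatic (pink-beam)
spectra and beam hardening, phase-contrast fringes, rotation-axis
wobble or drift, detector nonlinearity, scatter, rings from dead
columns, chemical kinetics of real acid attack, or sample motion other
than rotation. Passing tests therefore validate the algorithms and
their implementation, not the physics completeness of the model; on
real data the unmodelled effects above (and registration) are the
expected failure modes.

## Numerical choices and degenerate inputs

* Transmittance clamp ε = 10⁻⁶; clamped pixels counted as QC.
* Range/step commensurability tolerance 10⁻⁹ deg; angle-uniformity
  tolerance 10⁻⁶ relative in the reconstructor.
* Windows spanning < 180° are rejected ("insufficient angular
  coverage"); spans that are not multiples of 180° are accepted with
  the per-half-turn normalization (slight over-weighting of doubly
  covered angles, documented rather than hidden).
* An empty segmentation mask is a valid result (volume 0), not an
  error; an all-dead detector is a hard error.
* Contrast-free dissolution (residual fraction 1) changes no voxel and
  yields zero measured volume at all times — by construction of the
  ground-truth definition (strict decrease), not an artifact.
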