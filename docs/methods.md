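# Methods

## Problem setting

Given single-eye grayscale video, the pipeline estimates the pupil
center per frame and emits horizontal/vertical position-vs-time traces
suitable for reading nystagmus beats.  Per frame it (1) segments
{background, sclera, iris, pupil}, (2) classifies the blink state
(open / closing / closed), (3) extracts a sub-pixel center from the
pupil region with the iris as fallback, (4) gates out closed frames,
and (5) linearly interpolates the gaps.

All coordinates are raw image pixels: origin at the top-left pixel,
x rightward, y downward, pixel centers at integer coordinates.  No
pixel-to-degree calibration is attempted; traces are reported in pixel
space.

## Synthetic eye scenes

The renderer is the package's ground-truth source.  Geometry, chosen as
the simplest construction that produces all three ocular classes and
all three blink states:

- The eye opening is bounded by two parabolic eyelid arcs spanning
  ±45 px around the eye center with apex height 38 px at full aperture.
  As the aperture a ∈ [0, 1] decreases, the upper lid sweeps down
  across the opening (apex at 50 + 38(1 − 2a) px) while the lower lid
  stays put; at a = 0 the lids coincide and the opening is empty.  This
  mimics a real blink, where the upper lid does most of the travel, and
  guarantees that a uniform aperture draw produces closed frames with
  appreciable frequency (≈ 25% under U[0, 1], with open ≈ 15% and
  closing ≈ 60%).
- The iris is a disk (default radius 18 px) clipped by the opening; the
  pupil is a concentric disk (default 0.45 of the iris radius); the
  sclera is the opening minus the iris footprint.  Classes are
  mutually exclusive; each pixel is classified by its center.
- Gaze (θx, θy) ∈ [−40°, +40°]² maps linearly to center displacement,
  ±40° ↦ ±25 px on a 100-px image, per axis independently.  Linearity
  is the minimal camera assumption and makes the analytic center an
  affine function of gaze (verified to machine precision in tests).
- Blink labels follow iris-footprint visibility exactly: open iff every
  disk pixel lies in the opening, closed iff none does, closing
  otherwise.  "Iris" here means the full footprint (annulus + pupil),
  so closed ⇔ zero iris-class and zero pupil-class pixels.
- Appearance: flat gray levels (skin 0.55, sclera 0.92, iris 0.35,
  pupil 0.06 of full scale), one small specular disk on the iris, an
  optional multiplicative vertical illumination gradient, and additive
  Gaussian noise (default SD 6 gray levels), quantized to 8-bit.
  Identical parameters + seed give bit-identical frames.

The dataset generator draws parameters uniformly from fixed ranges
(gaze ±40° per axis, aperture [0, 1], iris radius 14–20 px, pupil ratio
0.3–0.6, noise SD 2–10, illumination gradient 0–0.25).  These ranges
are the package's standing study conditions for training and
evaluation.

What the renderer does **not** emulate: eyelashes, iris texture and
torsion, off-axis perspective foreshortening (the pupil stays circular),
motion blur, compression artifacts, and skin/iris appearance diversity.
Passing tests therefore demonstrate correctness of the pipeline
machinery and learnability of the synthetic domain, not clinical-grade
performance on real video.

## Nystagmus waveform

Jerk nystagmus is simulated as an ideal sawtooth: linear slow-phase
drift at a configurable velocity (deg/s per axis, signed), with an
instantaneous fast-phase reset to baseline every 1/beat-frequency
seconds, sampled at 1/fps spacing over [0, duration).  Positions are
clamped to the renderable ±40° span.  When the slow-phase velocity is
zero on an axis, the per-beat excursion amplitude defines the drift
instead (velocity = amplitude × beat frequency).  Real nystagmus has
finite fast-phase duration and velocity decay; neither matters for
testing center extraction and is omitted.

The canonical demo sequence is 20 s at 25 fps with baseline (−5°, +4°),
slow-phase velocity (20, −18) deg/s, 1.5 beats/s, and two scheduled
blinks of 13 frames each.  Within a blink interval the aperture ramps
linearly from its base value to 0 at the midpoint and back, traversing
open → closing → closed → closing → open.

## Segmentation and blink model

Both heads sit on a shared, fixed multi-scale encoder: raw intensity,
Gaussian-smoothed intensity at σ = 1, 2, 4, 8 px, gradient magnitude at
σ = 1, 2 px, and normalized pixel coordinates (9 features per pixel).
The segmentation head is a small MLP (hidden widths 16, 8 by default)
applied per pixel over standardized features; the blink head is an MLP
(64, 32) over pooled encoder maps — 20×20 block-means of the σ = 1 map
plus per-column profiles (covered fraction, topmost and bottommost
extent) of the dark iris/pupil-like region, which encode exactly the
lid-vs-iris relation the blink label is defined by.  A detached-head
ablation mode pools the raw image instead.

Training uses Adam with cross-entropy loss (scikit-learn's MLP
machinery), class-balanced pixel sampling (50 px/class/frame), and an
explicit per-epoch loop so train/val losses and validation mIoU are
logged per epoch; the best-validation-loss weights are retained.  All
training is CPU-scale: the default study (2,000 frames, 6 segmentation
epochs, 40 blink epochs) trains in ~20 s.  Fixed config seeds make
initialization, sampling and shuffling — hence entire histories —
bit-reproducible.

Design note: the heads are deliberately compact (≈ 5 × 10⁴ parameters
total) rather than a deep convolutional encoder–decoder.  On the
synthetic domain the classes are separable from local multi-scale
intensity structure, and a pixel-wise head keeps training deterministic,
fast and dependency-light; the module surface (build / train / predict /
export) is agnostic to the head's internals, so a heavier backbone can
replace it without touching the rest of the pipeline.

A trained model exports to a portable `.npz` weight bundle (layer
weights, standardization constants, encoder config) loaded by a
numpy-only runtime; portable and native predictions agree to < 1e−4
(in practice exactly, since the arithmetic is identical).  The FPS
micro-benchmark runs the portable model for a configurable number of
iterations with warm-up excluded; its numbers are host-dependent and
never used in acceptance checks.

## Center extraction

`fit_ellipse` performs a direct least-squares conic fit on the region's
outer boundary pixels (one-pixel erosion residue); if the boundary has
fewer than 6 points or the fit degenerates or runs away from the
region, it falls back to the image-moment centroid with axes from
second moments.  The fitted center matches the brute-force pixel
centroid within 0.5 px for solid rasterized ellipses with semi-axes
≥ 3 px (property-tested over random geometries).

For frames where the eyelids clip the region, boundary pixels adjacent
to the background class lie on the lid edge, not the true outline, and
are excluded.  The remaining free arc is fitted with a least-squares
circle (Kasa), which stays stable on partial arcs where an
unconstrained conic drifts by several pixels.  A fit is rejected — and
the center reported absent — when the free arc is under 25% of the
boundary or 10 pixels, when the fitted radius falls below 0.45× the
region's visible width or the fitted center leaves the image, or when
the arc subtends less than ~96° around the fitted center.  Absent
centers are handled by interpolation, which empirically beats keeping a
measurement whose occlusion bias can reach 10+ px.

Center source policy: pupil region if its area ≥ 20 px (at 100×100),
else the iris footprint, else absent.  Only the largest connected
component is fitted, guarding against speckle in model predictions.

Interpolation is linear per coordinate between the nearest flanking
measured frames; leading/trailing gaps hold the nearest value.  It is
exact on motion affine in time (tested to machine precision).  Trace
correlations are computed over all frames, interpolated ones included.

## Data handling

Frame containers are multi-page TIFF stacks or directories of image
files (lossless round-trip); corpora are PNG images + PNG label masks +
a CSV/JSON manifest with centers stored at 4 decimals.  Near-duplicate
removal follows a greedy streaming rule: keep the first frame, then
keep a frame iff its SSIM (standard settings, 8-bit data range) against
the most recently kept frame is below 0.8 — comparing to the last kept
frame rather than all kept frames keeps the scan O(n) and matches the
intent of removing temporal near-duplicates.  Images resize with
bilinear interpolation (anti-aliased), masks with nearest-neighbor.

Splitting is 80/10/10 per source: train = ⌊0.8 N⌋, the remainder halved
with the odd leftover frame assigned to test.  (Published per-source
tables are internally inconsistent on the odd frame — one source row
places it in validation, the blink-class rows place it in test; the
train counts, which all agree, are unaffected.)

## Numerical and degenerate-input choices

- IoU of two empty masks is defined as 1 (perfect agreement on absence)
  and flagged; mIoU excludes background by default.
- MAE/RMSE are computed over Euclidean center distances, so MAE ≤ RMSE
  always; per-axis variants follow from the trace CSV.
- Pearson r on a constant series raises instead of returning NaN.
- Blink AUC is one-vs-rest from predicted probabilities; a single-class
  truth raises.
- Per-pixel probabilities are exact softmax outputs and sum to 1 within
  1e−5 by construction.

## Problem sizes

Default study sizes — 2,000 training frames, 200-frame held-out test
split, 500-frame (20 s × 25 fps) trace sequences, 250 random ellipses
for the fit-vs-centroid comparison — were chosen so the full study,
training included, completes in well under a minute on one CPU while
keeping every estimate's sampling error far from the decision
thresholds.

## Known limitations

- The synthetic domain is easy by design; reported IoU/MAE values upper-
  bound what the same architecture would achieve on real eye video.
- The blink boundary (open vs closing) is defined by single-pixel iris
  clipping; frames within a pixel of the boundary are intrinsically
  ambiguous to an image-based classifier, which caps blink accuracy
  short of 1.
- Circle-based occlusion recovery assumes a near-circular pupil/iris
  outline; strong perspective foreshortening would bias it.
- Torsional (rotational) movement is out of scope: the renderer has no
  iris texture and the tracker extracts translation only.
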