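# Methods

## Problem setting

Unilateral facial palsy produces an asymmetric face and disordered muscle
recruitment. The package models a mirror-biofeedback session: a camera
frame is landmarked, the face's bilateral symmetry axis is estimated, the
affected half of the frame is replaced by the mirrored unaffected half,
and surface EMG of three mimic muscles (orbicularis oris, buccinator,
frontalis) is recorded while the patient performs a fixed gesture
protocol, once without and once with the mirrored display. Outcomes are
quantified as per-gesture activation maxima, percent changes between
conditions, and questionnaire scores.

## Landmark model

Landmarks follow the de-facto 68-point interchange layout. The schema
carries the structure the geometry needs: 29 bilateral pairs (jaw, brows,
nostrils, eyes, lips) and 10 midline points (chin tip, nose bridge,
columella base, mid lips), partitioning all 68 indices. Two midline
anchors (chin tip, top of nose bridge) orient the axis chin → forehead.
Coordinates are pixels, origin top-left, x right, y down, 0-based. The
detector is a plug-in interface rather than a bundled model: any callable
conforming to the `LandmarkProvider` protocol can supply points, and the
test suite uses an oracle provider that returns the synthetic generator's
ground truth. Meshes are Delaunay triangulations of the landmark points
only (no image-corner augmentation); degenerate (zero-area) simplices are
dropped, and cocircular ties follow Qhull's resolution with triangle
vertices stored in lexicographic order.

## Symmetry axis

For a bilaterally symmetric point set, the midpoint of every bilateral
pair and every midline point lies on the midline. The estimator therefore
fits a total-least-squares line (centroid + principal eigenvector of the
2×2 scatter) through the union of pair midpoints and midline landmarks,
with equal weights. Under unilateral droop, displaced points move
predominantly *along* the face's vertical, so pair midpoints slide along
the axis and the perpendicular fit degrades gracefully; the recovery
suite (100 random faces, tilt within ±30°, droop up to 0.1× the
interocular distance) requires ≤2° angular and ≤2 px perpendicular error
in at least 95 % of cases. When a schema offers fewer than two constraint
points the estimator falls back to the principal axis of all landmarks.
The estimator is exactly equivariant under rigid motions (the fit is
affine in the points), which the property tests check to 1e-6.

Reflection across the axis is the Householder map
`p' = a + 2((p−a)·d)d − (p−a)`, an involution to floating precision. Side
classification uses the sign of the 2-D cross product `d × (p − a)` with
an on-axis band of ±0.5 px; ties resolve to on-axis.

## Compositing

Which image half is "affected" cannot be inferred from a frame, so it is
an explicit input: the library takes an image side, and the CLI maps the
patient's anatomical side through a `--view {observer,selfie}` switch
(anatomical left = image right in observer view).

In the default `reflect_only` mode every affected-side pixel is sampled
from the input at its reflection across the axis with bilinear
interpolation; reflected samples falling outside the image default to the
original pixel. A linear feather of width 11 px (α from 0 to 1 across the
band, centered on the axis) joins the halves; outside the band the
unaffected side is bit-identical to the input and the affected side is
pure reflection. `mesh_warp` mode additionally estimates a
piecewise-affine transform from the mirrored landmark set to the original
landmarks over the Delaunay mesh and uses it inside the mesh hull — the
standard use of a landmark mesh when geometry, not just pixels, should be
mirrored. A `face_only` option restricts replacement to the landmark
hull; by default the whole half-image is mirrored, matching the
full-frame mirror appearance of a therapy display. Compositing is
deterministic: identical inputs produce bit-identical outputs.

## Synthetic faces

The generator places the 68 points from a fixed symmetric template
(proportions tabulated in `mirrorface/synthetic.py`, in units of the
interocular distance), applies droop, scales, rotates, and translates.
Droop displaces brow and mouth points by the full droop fraction and eye
points by half of it, downward in the face frame, emulating brow sag and
a downturned mouth corner; the ground-truth axis is the pre-droop midline
carried through the same similarity transform. The raster is drawn from
smooth analytic primitives (soft-edged ellipses and capsules over the
same landmark geometry) rather than polygon rasterization: every shape's
alpha is an even function of the signed distance, so a droop-free face is
symmetric about its axis to floating precision — the compositor's
fixed-point tests depend on this, and discrete polygon fills would break
it at boundary pixels. Default geometry is a 640×480 frame with a 120 px
interocular distance, matching a webcam-scale head. The generator is a
pure function of its parameters.

What the toy faces do *not* model: texture, lighting and shading
gradients, occlusions, landmark detector noise, and non-rigid expression
change. Passing the recovery suite therefore demonstrates correctness of
the geometry, not robustness to real-image landmark error.

## EMG chain

Filtering is a 4th-order Butterworth band-pass, 20–450 Hz, applied
forward–backward (zero phase) per channel; rectification is elementwise
absolute value; the envelope is a moving RMS with a 100 ms window and
50 ms step, stamped at window centers. These are conventional
surface-EMG choices. The protocol segmenter converts the fixed schedule —
kiss, smile, eyebrow raise, 5 s holds, 10 s rests, so gesture k occupies
[t0+15k, t0+15k+5) seconds — to exact half-open sample intervals at the
recording rate (1 kHz default). A gesture's activation is the maximum of
the RMS envelope within its cycle (a raw rectified maximum is available
behind a flag); values are kept in mV and also presented on a ×1000
integer scale (round-half-up), the microvolt dialect of clinical maxima
tables.

The synthetic generator programs a target amplitude per (gesture, muscle)
on the sine-amplitude scale: the RMS envelope plateau reads A/√2, as a
sinusoid of amplitude A would. Each muscle's carrier is a random-phase
multisine on a 10 Hz grid within 50–250 Hz — the band where surface-EMG
power concentrates. The grid spacing equals the reciprocal of the RMS
window, so every 100 ms window holds whole periods of every tone and of
every tone difference and the windowed RMS is exactly 1 wherever the
window falls; filtered Gaussian noise was rejected because its ~12 %
local-RMS wander biases a max-of-envelope statistic upward by several
percent and makes programmed amplitudes unrecoverable to the tolerance
the tests require. Channels use disjoint tone subsets, so synkinesis
mixing through the coupling matrix (source × target, diagonal 1) adds in
exact quadrature and the expected envelope peak of channel c in gesture g
is √(Σ_s (C[s,c]·A[g,s]/√2)²), which the generator returns as ground
truth. A Gaussian noise floor of 0.5 µV RMS is added; it keeps silent
channels below one table unit. The generator does not model motion
artifacts, electrode lift-off, fatigue-related spectral compression, or
non-stationary recruitment — recovery tests validate the analysis chain,
not robustness to those effects.

## Clinical scoring

The Facial Disability Index total is exactly
`((physical + social)/2)/100`, with a 2-decimal presentation value. The
item-level transform is configurable (the published item scoring is not
reproduced here): by default a five-item subscale maps linearly from the
all-minimum response anchor (0) to the all-maximum anchor (100), on a 1–6
response scale, with missing items either rejected or excluded-and-
rescaled. Percent change uses the without-biofeedback value as the base —
the only base consistent with the reference cases' reported reductions —
is flagged undefined for a zero base, and presents integer percentages by
round-half-up on the magnitude (68.75 → 69). Changes of at least 20 % in
magnitude are flagged clinically relevant. Cohen's d uses the pooled SD
with (n−1) weights; a zero pooled SD with unequal means is flagged
infinite rather than raised. The bundled five-case reference table is
reproduced as printed, including its missing cells (kept as missing and
excluded from change computation).

## Numerical and design notes

- The symmetric-face composite fixed point is exact because the default
  face center sits at ((w−1)/2, (h−1)/2): pixel centers reflect onto
  pixel centers and bilinear sampling degenerates to a copy.
- Axis serialization, provenance records and landmark files are
  plain JSON/CSV for reproducibility; every CLI run writes a provenance
  record sufficient to re-run bit-identically.
- Problem sizes in the test and acceptance suites (100 faces for axis
  recovery, 1000 draws for the involution/equivariance properties, 20
  generator seeds for EMG recovery, ~40 s synthetic recordings at 1 kHz)
  were chosen to exercise the statistics at comfortable margins while
  keeping the default suite fast on a single CPU.
- Known limitations: no temporal smoothing of the axis across frames
  beyond per-frame estimation; no color/lighting harmonization across the
  seam beyond feathering; first-face-only semantics (multi-face scenes
  are out of scope); no real-time latency guarantees.
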