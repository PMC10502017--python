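# Methods

## The measurement problem

A two-arm DNA origami hinge is a torsional spring: two stiff ~70 nm
arms joined by short single-stranded connections at a vertex, free to
fluctuate in the hinge angle θ.  Deposited on a TEM grid and imaged by
negative stain, an ensemble of such particles samples its angular
Boltzmann distribution, so the free-energy landscape follows from the
measured histogram by inversion, E(θ) = −k_BT ln p(θ) + C, and the
torque by differentiation, τ = −dE/dθ.  The package automates the two
measurement stages — finding analyzable particles and measuring each
one's angle — and the mechanics conversion.

## Coordinate and box conventions

Coordinates are continuous, 0-based, top-left origin, y down.  Boxes are
axis-aligned real rectangles stored center + size (the YOLO on-disk
convention after denormalization); IoU is computed on continuous
rectangles with no pixel quantization.  Angles are degrees in [0, 180],
computed as atan2(|cross|, dot) of the vertex→tip vectors — exact,
symmetric under tip swap, and invariant under similarity transforms.

The pixel calibration defaults to 1.4 nm/px at the 960-px working
scale, chosen so the nominal 70 nm arm spans 50 px; it is a required
configuration value, not a measured constant, and every spatial error is
reported in nm via this calibration.

## Synthetic micrographs

The generator defines the package's study conditions.  Each 960×960
scene contains, by default: 20 isolated target hinges (angles i.i.d.
from a truncated Gaussian, mean 90°, SD 15°, support [0, 180]°), 4
vertical distractors (a hinge seen edge-on projects as a single rod), 3
aggregates (2–3 overlapping hinges), 6 free blobs, and 3
boundary fragments — hinges whose bulk lies outside the frame, the
source of the elongated boundary detections the BBF exists to remove.
Particles are bright on a dark background (negative-stain polarity; an
`invert` flag flips it) over base level 0.25, long-wavelength mottle
(SD 0.03, ~120 px scale, emulating stain variation without any
electron-optics model) and i.i.d. pixel noise (SD 0.05, i.e. a
contrast-to-noise of ~9 for the 0.45 particle intensity).

Arms are rectangles sharing the vertex; the ground-truth vertex is the
intersection of the two *inner* arm edges and each tip is the inner-edge
endpoint, so the annotation rule used on real data holds exactly and
`angle_at_vertex` over the ground-truth keypoints reproduces the sampled
angle to 1e-6°.  The far end of each arm is chamfered by 15% of its
length ("fraying"), which makes tip localization intrinsically noisier
than the vertex — the behaviour observed in real annotation.  Ground
truth boxes are the enclosing square of the rendered particle.
Placement is rejection sampling with a 1000-attempt cap and a 10 px
clearance; failure raises an error naming the achieved count.  All
randomness flows from the config seed; a fixed config is byte-identical.

What the simulator does *not* emulate: contrast transfer, dose and
stain-chemistry effects, partially folded or broken particles, surface
crowding gradients.  Passing tests therefore demonstrate the pipeline's
internal consistency and its behaviour under controlled degradation,
not performance on real micrographs.

## Classical detection backend

Normalize → Gaussian blur (σ 2 px) → Otsu threshold → opening/closing →
connected components → per-component score.  A contrast guard (≥ 0.1
between foreground and background means) keeps Otsu from hallucinating
structure in particle-free images.  Components outside [0.25, 4]× the
expected two-arm area are discarded.  The confidence is the geometric
mean of

- an **area score**, exp(−((A − A₀)/(0.6·A₀))²) for expected area A₀, and
- a **two-arm shape score**: the fraction of component pixels within
  half an arm-width of the best two-segment (vertex + two arms) fit to
  the component's skeleton path, times a bend score
  1 − exp(−(bend/30°)²) that decays to zero as the two fitted segments
  become collinear.

Isolated hinges score ≈ 0.95–1.0; rods (edge-on hinges) die on the bend
score; aggregates die on the area score; blobs never reach the minimum
area.  Components passing a two-arm test are proposed as *squares*
(side = larger tight extent), mirroring the square annotation convention
a trained detector learns to reproduce; components failing it — and any
component touching the image border — keep their tight extent, which is
what gives boundary fragments their high-aspect boxes.  Post-processing
is the published recipe: inclusive confidence threshold 0.47, greedy
NMS at IoU 0.3 (ties broken by confidence, then smaller cx, then cy),
then the BBF (drop aspect > 1.5, re-square survivors).  The re-squaring
side defaults to 50 px in `bbf_filter` (the real data's annotation
convention) and to 80 px in the pipeline configuration (the enclosing
square of the synthetic geometry) — in both cases, the annotation box of
the data being processed.

## Classical pose backend

Each crop is binarized (Otsu), the largest component skeletonized, and
the longest geodesic skeleton path extracted by double BFS (this also
discards spurs).  A hinge skeleton is a single bent path; the optimal
two-run split (exact changepoint search minimizing summed
total-least-squares residual, O(1) per candidate via prefix sums)
locates the bend.  Each arm is refit excluding pixels within 32 px of
the bend and 16 px of the path end — the skeleton bends smoothly
through the vertex and curls inward at the frayed tip, and with the
naive fit those curved pixels tilt both arm directions toward each
other, producing a systematic ~2° underestimate of the angle; with the
exclusions the bias is below 0.1°.  The vertex is the intersection of
the two arm lines; because the skeleton follows arm *centerlines*, both
lines are shifted half an arm-width (estimated as component area /
skeleton length) toward the opposite arm and each tip extended by the
same amount, landing the keypoints on the inner-edge annotation
convention.  Fits with near-collinear arms (included angle outside
[20°, 160°]) or arms shorter than 30 px are rejected as not-a-hinge:
the estimator returns an all-missing pose with zero confidence rather
than a fabricated ~180° angle.

Keypoint confidence is exp(−rms/25 px) of the arm-fit residual (mean of
both arms for the vertex): a clean fit (rms ≈ 1.5 px at the 200-px crop
scale) scores ≈ 0.94, a contaminated one falls below the 0.92 gate.
The gate requires *all* angle-defining keypoints to pass — an angle
with one untrustworthy endpoint is untrustworthy.

SteriDyn devices use the same machinery with a three-run split
(arm–base–arm; the two changepoints are the vertices, searched exactly
in O(n²) with prefix sums); left/right labels are assigned by vertex
x-coordinate, and each arm angle is measured at its vertex against the
segment to the opposite vertex.  That four-point angle convention is an
interpretation (the geometry admits others) and is configurable via the
schema.  The nucleosome of a hinge-nucleosome device is located as the
most compact non-largest bright component (solidity ≥ 0.8), a position
point with solidity as its confidence.

Tip labels on a two-arm device are physically arbitrary;
`canonicalize_tip_labels` resolves a predicted pose against a reference
by minimal total tip distance (ties keep the original labels) and
reports whether it swapped.  The classical backend has no labeling
preference, so its flip rate is ~50% by construction; the package
measures flip rate but takes no position on what a learned backend's
rate implies.

## Mechanics

Angle histograms use right-open bins over [0, 180] with the last bin
closed (an exact 180° measurement is counted); the default 5° width is
a reporting choice, exposed in config and recorded in output metadata.
Boltzmann inversion sets E = −kT ln p on occupied bins, shifts the
minimum to zero (offset recorded), and leaves empty bins *undefined*
(NaN) rather than imputing them; an optional pseudocount (e.g. 0.5
counts/bin) is available when a fully defined landscape is required.
Torque is −dE/dθ by central differences within each contiguous defined
run, one-sided at run edges, in kT/degree; a kT→kcal/mol constant is
provided.  The two-sample KS statistic D is computed exactly by direct
ECDF comparison; the p-value uses the asymptotic Kolmogorov
distribution with effective size n_a·n_b/(n_a+n_b), adequate for the
hundreds-to-thousands regime this package targets and cross-checked in
tests against an independent implementation.

## Evaluation

Detection matching is greedy, confidence-ordered, one-to-one at
IoU ≥ 0.3 — the standard object-detection matcher, stated here because
published confusion counts rarely specify one.  Precision, recall and
F1 are kept at full precision and rounded only for presentation (2
decimals).  Undefined ratios are reported as null, not zero; the
degenerate all-wrong case reports F1 = 0 with a flag.  Pose evaluation
canonicalizes tips first, then reports per-keypoint error vectors in
nm, their two-dimensional standard deviation √(var dx + var dy)
(population variance; the mean radial error is reported alongside as an
alternative summary), the mean absolute angle error, and the flip rate.

## Problem sizes and determinism

The default study is 20 images × ~20 hinges (≈ 400 particles), chosen
to match a realistic single-condition dataset; it runs in well under a
minute on one CPU.  The distribution-level checks use 10⁴–10⁵ sampled
angles.  One master seed drives everything: per-stage seeds are derived
by hashing the stage name, per-image seeds are drawn from the stage
generator, so results are exactly reproducible and adding a stage never
perturbs another stage's randomness.

## Known limitations

- The classical backends are calibrated to the simulator's default
  geometry (50 px arms, ~7 px width); other geometries need
  `DetectionParams.from_simulation` or manual recalibration, and real
  micrographs will generally need a trained backend via the
  `DetectorBackend` / `PoseBackend` contracts.
- The bend score that rejects rods also penalizes genuine hinges with
  angles above ~160°; under the default angle law such angles are
  vanishingly rare, but near-open-hinge ensembles would need the
  two-arm angle range widened.
- Crops are similarity transforms only when the (clipped) box is
  square; a box clipped at the border resamples anisotropically and its
  angles are not preserved — such particles are normally removed by the
  BBF before cropping.
- The asymptotic KS p-value is inaccurate below a few tens of samples
  per group.
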