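# Methods

## Coordinate and indexing conventions

Pixels are 0-based with x = column, y = row and pixel centers at integer
positions; physical position (mm) = pixel × pixel spacing. Bounding boxes are
half-open. Public APIs index frames, rings and spokes 1-based (frame 1 = end
diastole, the strain reference); CSV outputs use the same convention.

## Landmark grid

The 168 landmarks are placed on 24 straight spokes radiating from the
centroid of the epicardial contour, at equal angular increments starting from
the septal midpoint (the circular mean of the two RV insertion-point angles,
taken on the shorter arc). Along each spoke, seven points sit at transmural
fractions r/8 (r = 1..7) between the endocardial and epicardial
intersections, i.e. strictly inside the wall. Spoke order is counterclockwise
in (x, y) by default (a flag flips it); spoke geometry for non-circular
contours is a design choice — straight rays from the centroid — since
"anatomic locations" does not constrain it further. Radial strain treats
rings 1 and 7 as the endocardial and epicardial landmarks; layer
circumferential strains use rings 2/4/6.

## Strain

Segment strain is Green (Lagrangian): ε = ((L_t/L₀)² − 1)/2, with an
engineering-strain switch (`formula="linear"`) for sensitivity checks.
Circumferential chords form a closed loop (24 segments including spoke
24 → 1). The slice circumferential strain is the midwall-ring average; a
7-ring average is emitted as an extra column (`eps_C_avg`). End systole is
the valid frame minimizing midwall ε_C, ties to the earliest frame — at
inference time the landmarks are the only available signal, so a
cavity-area-based definition is not used. Frames appended to reach the fixed
20-frame length are marked invalid and excluded from strain statistics and
from the training loss.

## Phantom

The myocardium is an incompressible annulus. A material point at ED radius R
maps to r(R,t) = √(R² − a(t)) with a(t) = R_endo² − r_endo(t)²; the in-plane
area between any two material rings is conserved exactly, and circumferential
and radial Green strains have closed forms (−a/2R², and
((Δr/ΔR)² − 1)/2 between the landmark rings). The contraction time profile is
a raised cosine from frame 1 to the ES frame with a partial raised-cosine
recovery (to 30% residual contraction at the last frame); the profile shape
only determines *when* strain values occur, not their correctness, because
every frame is evaluated against the same map. Twist is a rigid rotation
scaled by the same profile. A transmural twist gradient is available but
defaults to zero: the closed-form radial strain assumes rings 1 and 7 remain
on a common material ray, which a differential rotation would break.

Rendering: grid SPAMM, i.e. intensity = tissue level × (1 − d(t)cos²(πX₁/s))
(1 − d(t)cos²(πX₂/s)) where X is the reference position recovered through the
analytic inverse map, s = 6 mm tag spacing, and d(t) = 0.8·exp(−(t−1)/τ)
models tag fading (τ = 20 frames ≈ T1/frame interval). The blood pool is
bright and tag-free from frame 2 onward (washout); at frame 1 — the moment of
tag application — it carries tags. Background is dark. Noise is additive
Gaussian (sd 0.03 by default) with a Rician option; Gaussian is the default
for simplicity and because tag contrast, not noise statistics, dominates
tracking difficulty at these SNRs. Intensities are emitted in roughly [0, 1];
per-frame min–max normalization to [0, 1] is applied before any network
input.

Default conditions emulate a 1.5-T short-axis tagging protocol: 1.4 mm
pixels, 256 matrix, ~20 frames at 41 ms, 6 mm tag spacing, and a
mid-ventricular annulus (endo 25 mm, epi 40 mm) contracting by 30% of the
endocardial radius at frame 9, giving midwall ε_C ≈ −0.15. Dataset jitter
(uniform half-widths: 3 mm endo radius, 2 mm wall thickness, 10 mm center,
0.10 contraction, 3° twist, 1 frame ES timing, 0.01 noise sd) yields a
population spread of midwall ε_C of roughly 0.02–0.03, comparable to healthy
population variation. The septal direction is **not** jittered: the phantom
renders no right ventricle, so nothing in the image identifies the angular
origin, and a jittered origin would make the spoke labelling unlearnable —
this is exactly the ambiguity that dominates position (not strain) error in
real analyses. The train/val/test split is 90/10 followed by 80/20
(i.e. 72/18/10), deterministic given the seed.

What the phantom does **not** emulate: through-plane motion, LV outflow
tract anatomy, papillary muscles, receive-coil shading, respiratory
artifacts, non-circular wall geometry. Passing the desk-scale learning
benchmarks therefore demonstrates that the architecture, losses and pipeline
are implemented correctly and can be trained — not that the reduced models
would reach population-imaging accuracy on real acquisitions.

## Networks

All neural components are implemented directly in numpy (im2col convolution,
batch normalization, LSTM with full backpropagation through time, inverted
dropout, Adam) with hand-derived gradients; a finite-difference check of
every layer and of the composite loss is part of the test suite. Training is
bit-reproducible for a fixed seed.

*Localizer*: average-pool ↓8 → three stride-2 conv/batch-norm/ReLU blocks →
fully connected (ReLU, 20% dropout) → linear 4-output regression of the
normalized box corners (two-corner encoding; an axis-aligned box is fully
determined by 4 scalars). Loss: corner MSE. Adam at 1e-3, learning rate
× 1/√2 every 5th epoch after the 10th.

*Tracker*: shared-weight per-frame CNN (average-pool ↓4 → three stride-2
conv blocks with leaky-ReLU α = 0.1 → dense feature) → LSTM over the 20
frames → ReLU → linear per-frame head emitting 168 (x, y) pairs in
normalized crop coordinates. Default widths are reduced for CPU training
(feature 128, LSTM 128); both are configurable up to the full-scale 1024.
Loss: mean over valid frames of position MSE (mean squared Euclidean
distance over the 168 landmarks) + ω·[(ε̄_R error)² + (ε̄_C,mid error)²],
ω = 5 by default (configurable; 1/5/10 are plausible settings and the
published choice is ambiguous). Strain terms use frame 1 of each grid as its
own reference, so the loss is translation-invariant in its strain part and
fully differentiable. Adam at 1e-4 with ×1/√2 decay every 10th epoch at
full scale; the desk-scale runs in the tests use 1e-3 with the same
schedule, which suits the reduced widths.

Two initialization choices matter for small-budget training and are applied
always: regression-head weights are scaled by 0.01 so initial predictions sit
at the bias value, and the tracker head bias encodes a neutral annular layout
centered in the crop — this keeps the reference inter-landmark distances in
the strain terms well-conditioned from the first iteration (a constant-point
initialization makes the strain ratios blow up).

Training the tracker uses crops from the ground-truth (enlarged) box; at
inference the predicted box is used. The ED-frame box is applied to all
frames, which is safe because the heart is largest at ED.

## Statistics

Bias = mean of paired differences, precision = sample SD (n−1; the
denominator is a package choice), limits of agreement = bias ± 1.96 ×
precision. Group contrasts use scipy's two-sided t tests (Student pooled or
Welch with Welch–Satterthwaite df) with 95% CIs; the Bonferroni threshold is
α/m (0.05/15 ≈ 0.0033 for the canonical 15-comparison protocol). Differences
are computed per slice.

## Numerical notes and desk-scale sizes

- The annulus inverse map is analytic; no numerical inversion anywhere.
- Strain equivalence between the tracked-grid computation and the closed
  form is exact to ~1e-15 on phantom grids (chord/radius cancellation for
  concentric equally spaced rings); tests assert 1e-9.
- Crop/resample uses cubic-spline interpolation; its coordinate transform is
  affine and round-trips to 1e-9.
- The test-suite study uses 200 phantoms with reduced widths (localizer 30
  epochs, tracker 60 epochs, batch 8–16), chosen so a full session trains in
  a few CPU-minutes while still exercising every training-path branch.
- Degenerate inputs: coincident or antipodal RV insertion points, spokes
  missing a contour, empty masks, zero-area boxes, nonpositive reference
  lengths and invalid reference frames all raise explicit errors.

## Known limitations

Reduced-width models and a geometric phantom put a floor on realism; the
localizer and tracker would need the full-width architectures, augmentation
and real tagged data to approach reader-level precision. Only one slice is
processed at a time (no basal/apical exclusion logic), segmental (AHA)
strain and longitudinal strain are out of scope, and the 20-frame temporal
normalization discards frames beyond the 20th rather than resampling.
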