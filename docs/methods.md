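# Methods

This note records the models, conventions and parameter choices behind
`leafgrade`, the points where the design was genuinely open, and what the
synthetic tests do and do not demonstrate about real leaves.

## Imaging model and segmentation

The pipeline assumes the acquisition discipline of a grading cabinet: one
leaf per frame, lying flat on a uniformly lit near-white board, nominally
512 × 512 px. The board colour is *metadata* (default RGB 250, 250, 250),
not re-estimated per image: the disfigurement feature is defined by
comparison against the known background, and an unambiguous background is
what the controlled cabinet provides.

Segmentation thresholds the Euclidean RGB distance from the background
(Otsu's method on the distance map by default) and keeps the largest
8-connected component. Holes in the leaf — pixels coloured like the board
— remain background, so the colour and texture features are computed over
intact lamina only. If a second above-threshold object of at least 80 % of
the largest one's size is present, contour extraction refuses with an
ambiguity error rather than guessing.

## Edge detection and the contour

Edges are localised at the zero-crossings of a single sampled
Laplacian-of-Gaussian kernel. Defaults: σ = 2 px, kernel radius
⌈4σ⌉ (at that truncation the coefficients sum to ~1e−4, so flat regions
produce near-zero response). Convolution uses mirror boundary extension to
avoid dark-frame artefacts.

The filter is applied to the *binarized* image (the method's processing
order: colour → binary → LoG → contour). Of the two pixels flanking each
sign change, the foreground-side pixel is marked, which places the edge
exactly on the object's own boundary pixels; a gradient-magnitude gate
(5 % of maximum) suppresses sign flips of the numerically-zero response in
flat areas. The largest edge component is flood-filled and its outer
boundary traced with a Moore-neighbour walk (Jacob's stopping criterion),
yielding a closed, ordered, 8-connected, duplicate-free pixel cycle with
interior points eliminated — oriented so the shoelace area (col as x, row
as y) is positive. If the zero-crossing component fails to enclose a
region, the boundary of the segmented mask itself is traced instead; the
two paths agree on every synthetic image we generate, and the fallback
exists for robustness on degraded input.

Contour length is estimated with the Vossepoel–Smeulders corrected chain
code (0.980 per axial step, 1.406 per diagonal, −0.091 per direction
change). The raw Freeman chain (1/√2 weights) overestimates smooth
digitised curves by ~5 % and is exposed separately as `chain_length()`.

## Shape features

The closed contour is simplified by recursive farthest-point splitting
(closed-curve Ramer–Douglas–Peucker) with point-to-*segment* deviation and
a default tolerance of 2 px — at the areas and perimeters of real graded
leaves (~300–1750 px perimeters) this distorts the perimeter by well under
1 %. The polygon is fan-triangulated from its first vertex with *signed*
triangle areas; their sum equals the whole-polygon shoelace for any simple
polygon, convex or not, so no ear clipping is needed. A quadratic
segment-intersection check rejects self-intersecting polygons (skipped
beyond 400 vertices, where the polygon is a dense contour copy that
inherits simplicity from the trace).

* **Area** = |Σ signed triangle areas|, rounded to integer pixels. Because
  vertices sit on boundary pixel centres and chords cut inside convex
  arcs, the estimate runs ~1–3 % below the continuous area of an ideal
  disk; tests budget 3 %.
* **Perimeter** = number of pixels of the 8-connected rasterisation of the
  polygon sides, shared vertices counted once (an axis-aligned square of
  side 100 gives exactly 400). A side at angle θ covers max(|cosθ|,|sinθ|)
  pixels per unit length, so this count is exact for axis-aligned sides
  and runs ~10 % low on average for isotropic orientations (envelope
  1/√2..1). It is a grading *feature*, not a length estimator; the
  corrected contour length above serves that purpose.
* **Disfigurement** = 100 × (background-coloured interior pixels) /
  (interior pixels), interior meaning strictly inside the polygon
  (scan-line fill minus the rasterised boundary). Background matching
  tolerates |Δ| ≤ 10 per channel, absorbing anti-aliasing at hole rims.
  Against generator ground truth the measurement is accurate to ≪ 0.5
  percentage points.

## Texture features

Luminance (BT.601 weights, rounded) is degraded from 256 to 32 grey levels
by `level = ⌊g/8⌋` — purely to shrink the co-occurrence matrix to 32 × 32.
The GLCM is directional (not symmetrised): entry (i, j) counts pairs where
the pixel of interest has level i and the pixel at displacement
δ = (DX, DY) has level j, both inside the leaf mask; the default δ = (1, 0)
pairs each pixel with its right-hand neighbour. Energy, entropy and
contrast are computed on the probability-normalised matrix (Haralick
convention); entropy carries the conventional minus sign and base-2
logarithm so it is nonnegative and in bits. Dialect flags reproduce the
historical variants: `raw=True` computes on raw counts, and
`as_printed=True` drops the entropy minus sign.

## Membership networks

Architecture is fixed at 3 inputs → 5 logistic hidden units → 3 logistic
outputs, one net per factor category. Inputs are min–max scaled to [0, 1]
on the training set (raw magnitudes — areas ~10⁴ versus energies ≲ 1 —
would saturate the sigmoids); evaluation values clip into the training
box. Training is online stochastic gradient descent on squared error with
one-hot targets, fixed data order, learning rate 0.5, weights initialised
uniform(−0.5, 0.5) from the seed — bit-reproducible. Training stops when
every training example is argmax-correct *with a winning margin of at
least 0.3* (ties count as incorrect), or at `max_epochs` (5000 default;
1500 in the experiment harness) with a warning. The margin matters: a
bare argmax stopping rule halts with near-uniform outputs and
uncalibrated memberships.

**Per-feature membership rows.** The evaluation matrix needs one
membership row per *individual* feature, while the net consumes three
features jointly. Row j is built by class-conditional probing:
r<sub>jc</sub> is the net's class-c output with input j at its observed
value and the other two inputs clamped at class c's own training means,
the row then renormalised to sum to one — the net acting as a
compatibility oracle ("how strongly is grade c supported when feature j
looks like this and the rest of the category is typical of c?"). The
obvious alternative — clamping the other inputs at the *global* training
mean — was implemented first and rejected on evidence: any class whose
features occupy the middle of the scaled space wins every mid-space probe
regardless of the observed feature, and end-to-end grading collapsed to
near-chance even with perfectly trained nets.

## Fuzzy comprehensive evaluation

Composition is the weighted average M(·,+): Bᵢ = Aᵢ·Rᵢ and V = A·B as
ordinary matrix–vector products. With unit-sum weights and unit-sum
membership rows this conserves mass exactly (every Bᵢ and V sums to 1),
and it reproduces the hand-checkable worked evaluation; max–min
composition does neither and is deliberately not offered. The engine is
generic in the number of categories and classes (≥ 2); the 3 × 3 × 3
layout with weights A = (0.35, 0.2, 0.45), A₁ = (0.3, 0.4, 0.3),
A₂ = (0.4, 0.3, 0.3), A₃ = (0.3, 0.3, 0.4) is the shipped default.
Normalised V components are reported to 4 decimals, B to 2, matching the
reference presentation; internal arithmetic is double precision. Argmax
ties break toward the earliest declared class, with a warning.

The shipped worked-example fixture contains printed values that are
internally inconsistent with the stated composition arithmetic (three B
cells and the middle V component; the other V components agree with
recomputation exactly). Recomputed values are authoritative throughout the
package; the printed ones are preserved verbatim in the fixture with
discrepancy notes.

## Synthetic leaves

The generator emulates the cabinet: a simply connected blob — an ellipse
with five Fourier boundary harmonics, sampled in continuous coordinates,
rasterised on the canvas — filled with a class-dependent base colour,
modulated by a correlated multiplicative luminance field (Gaussian-filtered
white noise, unit variance on the lamina) plus independent per-channel
noise, with circular holes carved from the interior. Hole placements that
would touch the boundary are rejected (topology and the outer perimeter
stay intact), and carving proceeds with shrinking radii (10 → 2 px) until
the achieved fraction is within ±5 % relative of the target; scattered
single-pixel holes are a last resort for tiny targets. Ground truth
(blob pixel area, traced boundary length, exact background-coloured
interior fraction) is measured on the emitted raster, not the continuous
model, so it is exactly what a perfect extractor could recover.

Default class specs were calibrated once against the published feature
tables of real graded leaves: major axes 170–300 px with aspect 0.55–0.75
put areas inside the printed 10 803–59 146 px range and perimeters inside
289–1750 px; hole fractions 0.02 / 0.06 / 0.04 sit inside the printed
disfigurement range 0.56–9.47 %; and (base colour, noise amplitude,
spread) triples keep every channel variance inside the printed ~65–186
envelope while giving the three classes distinct colour-variance
signatures. Texture grain (correlation length 1.5 / 5 / 14 px) separates
the classes in GLCM statistics.

**What the synthetic experiment shows — and does not.** With these
defaults, 100 training + 50 held-out leaves per run over ten seeds, the
full pipeline reaches mean training accuracy ≥ 0.9 (in practice 1.0) and
held-out accuracy far above the ⅓ baseline. This validates the machinery:
features are measured correctly, nets converge, the FCE decision follows
the evidence. It does *not* reproduce the published 94 % / 72 % accuracy
on real leaves — that image database was never deposited — and synthetic
classes are cleanly separated where real grades overlap: venation,
illumination gradients, specular highlights, wrinkles and multi-modal
within-grade variation are all absent by design.

## Numerical conventions and degenerate inputs

* Coordinates are 0-based (row, col); GLCM displacement (DX, DY) is in
  (column, row) order so δ = (1, 0) means "one pixel right".
* Colour variance is population (1/n) variance; at leaf-region sizes the
  sample/population distinction is far below measurement noise, but the
  convention is fixed.
* 0·log 0 := 0 in the entropy; a GLCM with no valid pairs, an empty leaf
  mask, an all-background image, a collinear contour, a polygon without
  interior pixels, and training data missing a class each raise a typed
  error rather than returning a value.
* Every random draw (generation, weight init) descends from one top-level
  seed through named `SeedSequence` substreams; derived seeds stay below
  2³¹. Identical configuration ⇒ byte-identical images, weights, reports.

## Known limitations

* Grades whose distinguishing signal lies mostly in the *joint*
  distribution of a category's features lose information in the
  per-feature membership rows; the category nets see the joint vector,
  but the FCE consumes per-feature rows by construction.
* The pixel-count perimeter feature is orientation-dependent (exact for
  axis-aligned sides, ~0.71× for diagonals); consistent within a dataset
  but not comparable across rotations of the same leaf.
* The LoG contour path assumes high edge contrast against the board; on
  low-contrast input the mask-boundary fallback silently takes over.
* Single-leaf frames only; no shadow removal or illumination correction.
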