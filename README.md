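# leafgrade

Automatic grading of flue-cured tobacco leaves from images, by two-level
fuzzy comprehensive evaluation (FCE).

Commercial tobacco leaves are graded by experts into codes such as **X1L**
(lugs, lemon hue, first grade), **B4L** (upper leaf, lemon, fourth grade) or
**S1** (scrap), judging size, shape, surface damage, colour and texture by
eye. `leafgrade` implements a machine-vision version of that judgement: a
leaf photographed flat on a white board is reduced to nine features, each
feature is converted into fuzzy membership grades over the candidate
classes by a small neural network, and a hierarchical fuzzy evaluation
combines the grades into a decision.

## The method

**Features.** Nine features in three categories:

* *shape* — surface area, surface perimeter and disfigurement. The leaf
  contour is found at the zero-crossings of a Laplacian-of-Gaussian filter,
  `LoG(x,y) = -(1/πσ⁴)(1-(x²+y²)/2σ²)·exp(-(x²+y²)/2σ²)`, applied to the
  binarized image; the closed contour is simplified to a polygon
  (Ramer–Douglas–Peucker), and area, perimeter (pixels of the rasterised
  polygon sides) and disfigurement (% of interior pixels coloured like the
  background — holes and damage) are measured on the polygon.
* *texture* — energy `E = Σ p²ᵢⱼ`, entropy `H = -Σ pᵢⱼ log₂ pᵢⱼ` and
  contrast `C = Σ (i-j)² pᵢⱼ` of the 32-level grey-level co-occurrence
  matrix (GLCM) at displacement δ = (1, 0).
* *colour* — the per-channel variances of R, G and B over the leaf region.

**Memberships.** One 3–5–3 sigmoid back-propagation network per category
maps its three features to support for each class; it is trained online on
one-hot targets until every training specimen is classified correctly.
Per-feature membership rows r<sub>ij</sub> (rows sum to 1) are read off by
class-conditional probing of the trained net.

**Decision.** With sub-factor weights A₁ = (0.3, 0.4, 0.3),
A₂ = (0.4, 0.3, 0.3), A₃ = (0.3, 0.3, 0.4) and category weights
A = (0.35, 0.2, 0.45) (colour weighted highest, texture lowest):

    Bᵢ = Aᵢ · Rᵢ        (one-level evaluation, weighted average)
    V  = A · B,   V ← V / ΣV,   grade = argmax V

Because no real graded-leaf image database is publicly available, the
package ships a synthetic-leaf generator with exact per-image ground truth
(area, perimeter, hole fraction), calibrated to the published ranges of
real graded leaves; every pipeline stage is tested against it.

## Worked example

The package replays a published hand evaluation of one test leaf from its
nine membership grades:

```bash
leafgrade demo-worked-example
```

prints

```
One-level evaluation matrix B (rows: shape, texture, colour):
  0.23  0.57  0.20
  0.23  0.56  0.21   (printed: [0.23, 0.53, 0.21])
  0.24  0.56  0.20   (printed: [0.26, 0.54, 0.2])
Two-level evaluation vector V: 0.2345  0.5635  0.2020   (printed: [0.2345, 0.5575, 0.202])
Normalised V: 0.2345  0.5635  0.2020
Decided grade: B4L
```

Each row of **B** is one factor category's weighted membership over
(X1L, B4L, S1); **V** combines them with the category weights. The leaf is
graded **B4L** with membership 0.56 against 0.23/0.20 for the
alternatives. The `(printed: ...)` annotations flag cells where the source
table's printed numbers are internally inconsistent with its own
composition arithmetic; `leafgrade` pins the recomputed values and ships
the printed ones in its fixtures.

A full synthetic experiment (generate leaves, extract features, train the
three nets, grade a trained and a held-out group):

```bash
leafgrade experiment --seed 1 --out report/
```

which reports, for the shipped default classes, training and held-out
accuracy with confusion matrices (1.000 / 1.000 at seed 1 — the synthetic
classes are cleanly separated; real leaves are harder).

Other subcommands: `generate` (synthetic images + ground-truth manifest),
`extract` (images → nine-feature CSV), `train` (CSV → three model JSONs),
`grade` (features + models → decisions).

## Layout

```
src/leafgrade/
  synthetic.py    synthetic leaf generator with exact ground truth
  edges.py        LoG kernel, segmentation, closed-contour extraction
  shape.py        polygon fitting; area, perimeter, disfigurement
  color.py        per-channel variance features
  texture.py      grey-level degradation, GLCM, texture statistics
  membership.py   3-5-3 backprop nets and membership matrices
  fce.py          weight sets, one/two-level composition, decision
  fixtures.py     transcribed reference tables (data/*.csv)
  pipeline.py     feature extraction, experiment harness, worked example
  cli.py          the `leafgrade` command
docs/methods.md   model assumptions, parameter choices, limitations
```
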