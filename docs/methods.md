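# Methods

## Measurement model

An implant on a periapical radiograph is summarised by three landmarks:
A and B at the ends of the platform chord (the implant body diameter,
excluding thread depth) and C at the apex. The radiographic diameter is
D = |AB|; the radiographic length is the perpendicular height of C over
the line AB, computed as L = 2S/D from the absolute shoelace area S of
triangle ABC. Working through the triangle area rather than |PC| for some
platform midpoint P makes L independent of where along AB the chord was
annotated and exactly invariant under image rotation and translation.
Coordinates are continuous (annotation tools emit sub-pixel vertices);
the image y-axis points down, which is immaterial because distances and
absolute areas are orientation-invariant. Pixel values are converted to
millimetres with the detector's Imager Pixel Spacing, a single scalar:
row/column spacings within 0.5% relative are averaged, larger anisotropy
is rejected (intraoral sensors have square pixels; a genuinely
anisotropic source would need axis-resolved handling that the single-D,
single-L model cannot express).

Radiographic dimensions are deliberately *not* corrected back to true
dimensions. Magnification and angulation are unobservable per image, so
the classifier operates on the distorted measurements and absorbs the
distortion into the cluster geometry.

Degenerate inputs: coincident A and B raise a degenerate-segment error;
triangles with area < 1e-9 px² are treated as collinear and rejected. A
record whose measured L does not exceed its measured D triggers a warning
(not an error): every catalogue size is longer than wide, so this usually
indicates a vertex-order mistake, but extreme foreshortening can produce
it legitimately.

## Classifier

Feature vectors (D, L) in mm are stretched by f(D, L) = (wD, L), w > 0.
The catalogue's diameter increments (0.7–0.8 mm) are much smaller than
its length increments (2 mm), so at w = 1 the Euclidean metric is
dominated by length variance and clusters cut across diameter groups;
w rebalances the axes without touching the length component.

k-means++ is implemented directly rather than wrapped:

- **Seeding**: first centroid uniform over the points, each next one
  drawn with probability proportional to the squared distance to the
  nearest chosen centroid. The classic seeding law, without greedy local
  trials, so the seeding distribution is exactly the D² law (this is also
  what the empirical-distribution test checks).
- **Lloyd iterations**: nearest-centroid assignment, mean update; stop
  when the relative inertia change is below `tol` (default 1e-6) or after
  `max_iter` (default 300). An emptied cluster is re-seeded with the
  point farthest from its assigned centroid.
- **Restarts**: `n_init` = 10 by default; each restart draws an
  independent child seed from a `SeedSequence`, so a fit is
  bit-reproducible from one integer seed. The lowest-inertia run wins;
  ties keep the earliest restart.

k = 9 (one cluster per catalogue size). The cluster → size-code map is
the total-agreement-maximising bijection on the training contingency
(found by linear assignment); among ties the lexicographically smallest
code sequence is chosen so the map is deterministic. A bijection is the
right structure because nine clusters must cover nine codes even when a
cluster ends up empty on training data. Prediction is
nearest-centroid in the stretched plane; exact ties go to the lowest
cluster index.

The weight grid defaults to the integers 1…10 (configurable, including
non-integer steps). Selection follows the benchmark protocol —
accuracy on the held-out test split — with the option of selecting on a
validation split instead; accuracy ties resolve to the smallest w.

## Evaluation

One-vs-rest per code: TP is the diagonal cell, FN/FP the remaining
row/column mass, TN the rest. Accuracy, sensitivity, specificity, F1,
PPV, NPV follow the standard ratio definitions, with any
zero-denominator metric defined as 0. A hard classifier yields a
one-point ROC, so AUC = (SE + SP)/2 exactly (this identity is asserted,
not approximated). The 95% CI uses the DeLong placement-value estimator
on the two-valued score, with sample (n−1) variances and z = 1.96,
clipped to [0, 1]; the variance is zero exactly when the code is
classified perfectly, collapsing both bounds to 1. Displayed tables
round half-up to 3 decimals; raw values are retained in the machine
output.

The before/after comparison builds, per code, the 2×2 table
(model × one-vs-rest correctness) and applies Pearson chi-square without
continuity correction, flagging p < 0.05. This is one defensible
construction of such a comparison — the underlying published analysis is
not specified precisely — and the output is labelled accordingly. A
degenerate table (zero margin) reports statistic 0, p = 1, with a warning.

`implantsize.reference` carries the published per-code counts of the two
benchmark classifier arms (a fine-tuned CNN and the clustering pipeline)
on their shared 180-image test set; the test suite and the acceptance
script recompute the full published metric table, every CI bound and
both total error counts (2 and 5) from those counts alone.

## Synthetic data generator

The generator emulates what makes the problem nontrivial: the projection
of a rigid catalogue implant onto the sensor plane. For each record it
draws magnification m ~ U[1.05, 1.20], sensor-implant angle
θ ~ N(0, 8°) truncated at ±25°, and in-plane rotation φ ~ U[−20°, 20°];
projects D_rad = d·m and L_rad = l·m·cos θ (foreshortening applies to
the long axis only — the platform chord is modelled as sensor-parallel,
the simplest projection consistent with intraoral geometry); places the
platform midpoint uniformly on a 768×1024 px canvas at 0.04 mm/px
(retrying placement, then erroring if the implant cannot fit); and adds
i.i.d. Gaussian noise (sd 0.5 px) to all six coordinates. The
distribution parameters are package defaults chosen to be clinically
plausible for the paralleling technique, not measured values; they are
config-exposed for sensitivity analysis.

The benchmark-scale preset produces 1320 records (147 for the first six
codes, 146 for the last three — near-balanced with every class ≥ 40, so
the canonical 20+20-per-class split yields 960/180/180). A low-noise
preset (m within ±2%, θ sd 2° capped at 5°, 0.25 px noise) produces a
nearly separable dataset used for parameter-recovery checks; a noiseless
config (m = 1, θ = 0, no noise) makes extraction recover catalogue
dimensions to 1e-9 mm and anchors the round-trip tests.

What the generator does **not** emulate: actual radiograph pixels,
thread/apex appearance, healing abutments or superstructures, annotator
bias in landmark placement conventions, and any correlation between
angulation and jaw region. Passing synthetic tests therefore validates
the geometry, the classifier and the evaluation arithmetic — not
clinical performance on real radiographs.

## Problem sizes and determinism

Test-suite and acceptance runs use the benchmark-scale dataset (1320
records; tuning = 10 weights × 10 restarts on 1140/960 training points)
and a 540-record low-noise dataset over 5 seeds; exhaustive oracles are
kept tiny by design (≤ 3¹² assignment enumerations, 9! permutations,
10⁴ seeding draws). Every random stage — generation, splitting, seeding,
restarts — derives from named `SeedSequence` children of a single
integer seed, so identical seeds give bit-identical models, predictions
and on-disk datasets.

## Known limitations

- The classifier has no reject option: an out-of-catalogue implant is
  forced into the nearest of the nine clusters.
- Tuning on the test split (the benchmark protocol) leaks the selection
  signal; the validation-split option exists for stricter use.
- The cos θ foreshortening model ignores tilt about the long axis and
  nonplanar sensor placement.
- At default distortions the diameter groups barely overlap, so
  synthetic accuracy is optimistic relative to the published clustering
  arm (which errs 5 times in 180); the error *structure* — same-diameter,
  adjacent-length confusions — matches.
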