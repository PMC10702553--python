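# Methods

This note documents the models, conventions and numerical choices behind
`gratio`, and what its phantom-based validation does and does not show.

## The measurement problem

In semi-thin cross-sections of peripheral nerve, every myelinated fiber
appears as a bright axon surrounded by a dark (PPD) or mid-tone (TB) myelin
ring. The g-ratio — the ratio of the inner (axon) to the outer
(axon + myelin) diameter — summarizes relative myelin thickness and sits
near 0.6–0.7 in healthy nerve. Estimating it at scale requires (i) a
3-class semantic segmentation of the section, (ii) a per-fiber instance
decomposition, (iii) automatic rejection of fibers that are unsuitable for
morphometry (obliquely cut, incomplete, or too small), and (iv) per-fiber
measurements with a reliability assessment. `gratio` implements this chain
and ships a phantom generator so that every stage can be validated against
exact ground truth.

## Phantom generator

A scene is a set of non-overlapping fibers on a background. Each fiber is
an elliptical axon (semi-axes `a >= b`) inside a concentric outer ellipse
(`A = a/g`, `B = b/g` for design g-ratio `g`, default 0.6); the ring
between them is myelin. Rasterization uses a pixel-center-inside test, so
a pixel belongs to the ellipse iff its integer center does — area oracles
in the tests count pixels with exactly this rule and agree exactly.

Placement is rejection sampling: a candidate is accepted only if its
support stays at least `min_gap_px` (default 1) pixels from every placed
fiber; after 500 failed attempts per fiber the generator raises an error
naming the density limit. Clean fibers draw the axon equivalent radius
uniformly from `radius_range` (default 8–20 px) and an aspect ratio
`a/b` from `aspect_range` (default 1.0–1.2, eccentricity at most ~0.55).

Three defect types emulate the structures the selection filters must
reject, each constructed strictly beyond its threshold:

* **oblique** — `b = a/4`, continuous eccentricity `sqrt(1 - 1/16) ~ 0.968 > 0.95`;
* **incomplete** — a 120° wedge removed from axon and myelin; the notched
  axon's solidity is ~0.71 < 0.9 while its area and eccentricity stay
  acceptable;
* **undersized** — circular axon with radius 3.2–3.7 px, area ~32–43 px
  < 50 even after rasterization jitter, while remaining round and compact.

Requested defect fractions are rounded to exact counts
(`round(fraction * n_fibers)`); the remainder are clean. One seeded
generator drives geometry, placement and rendering, so equal seeds give
bit-identical scenes.

Appearance is stylized, not photorealistic: PPD-like scenes use a dark
ring (0.12) / mid-gray axon (0.55) / light background (0.92); TB-like
scenes use a mid ring (0.45) / lighter axon (0.70) / mottled background
(low-frequency Gaussian field, ±0.05). Optional Gaussian blur and additive
Gaussian noise (clipped to [0, 1]) mirror the smoothing/noise variability
of scanned sections. The phantoms deliberately omit Schwann cell nuclei,
blood vessels, stain gradients, unmyelinated axons and touching fibers
(a configurable gap keeps supports disjoint), so passing tests demonstrate
correctness of the measurement chain — not segmentation performance on
real histology, which depends on a model trained on real annotations.

True morphometrics use area-equivalent radii: `r_eq = sqrt(a b)`,
`R_eq = sqrt(A B)`, so `true_g = r_eq / R_eq` equals the design `g` and
reduces to `r/R` for circles; diameters and ring width scale by the pixel
size (default 0.05 μm/px).

## Segmentation

Two interchangeable backends produce per-class probability maps
(background, myelin, axon; per-pixel sum 1 within 1e-5):

* **Network.** A U-Net with two 3×3 convolutions per depth, each followed
  by batch normalization and PReLU; 2× max-pool downsampling and
  nearest-neighbour upsampling with a channel-halving convolution and
  concatenated skip connections; softmax over 3 classes. The full
  configuration has six depths (16, 32, 64, 128, 256, 512 filters) with
  512-px patches; training uses soft multi-class Dice loss and Adam at
  learning rate 1e-3, with augmentations (90° rotations plus free ±15°
  rotation, flips, zoom 0.9–1.1, Gaussian noise and smoothing). The
  network is implemented directly in numpy with hand-written backward
  passes; every layer's gradient is verified against central finite
  differences (tolerance ~1e-6 relative) in the test suite. Because the
  implementation is pure numpy on one CPU, the test suite and the
  documented experiments use a reduced three-depth 8/16/32 variant on
  256-px patches (`TrainConfig.reduced()`, 25 epochs, flips + rotations
  only); the full configuration remains constructible and trainable.
  Weights are never shipped; reproducibility comes from seeding weight
  initialization, shuffling and augmentation from one generator —
  identical seeds and data give bit-identical metric logs.
* **Oracle.** Converts a ground-truth mask into near-one-hot maps
  (confidence 0.99) with optional seeded corruption that re-labels exactly
  `floor(flip_rate * H * W)` pixels. At `flip_rate = 0` the argmax
  reproduces the mask exactly, which makes the oracle a perfect-
  segmentation test double for everything downstream.

Inference tiles large images with a cosine-tapered blending window in the
overlaps and renormalizes per pixel; inputs are reflect-padded to the
pooling divisor. On phantom interiors the tiled and whole-image
predictions differ by less than 0.2 in probability (asserted in the
acceptance tests).

## Post-processing

Probability maps become a label mask by thresholding at 0.8: a pixel is
assigned to a class whose probability reaches the threshold, with priority
axon > myelin > background when several pass or tie. Pixels where no class
reaches 0.8 are assigned by argmax rather than forced to background —
forcing background would fragment thin myelin rings.

Cavity filling then relabels enclosed background components (4-connected,
not touching the border) with area **greater than** 5 px to the majority
class among their 8-neighbours. Filling *large* holes and keeping small
ones is the literal reading of the rule this stage implements; because the
common image-processing convention is the opposite, the direction is
switchable (`fill_direction="smaller"` fills holes of at most the
threshold area). The operation is idempotent and never converts foreground
to background. Hole detection uses 4-connectivity against 8-connected
foreground, the standard digital-topology duality.

## Fiber instances and selection

Each 8-connected axon component seeds one fiber; ids follow row-major
discovery order. Myelin pixels are assigned to the geodesically nearest
axon component through the axon-or-myelin support, computed as a seeded
watershed on a constant image (equivalent to multi-source BFS; verified
against a brute-force BFS oracle in the tests, with ties allowed to go to
either side). Myelin with no reachable axon is reported separately rather
than guessed.

Shape descriptors come from the axon region's second central moments
(eccentricity of the inertia ellipse) and convex hull (solidity), the
regionprops semantics. A fiber is excluded iff eccentricity > 0.95,
solidity < 0.9, or area < 50 px — strict inequalities, so boundary values
(0.95, 0.9, exactly 50 px) are retained. All triggered reasons are
recorded. Fibers touching the image border are kept by default; an
`exclude_border` flag exists because partially captured border fibers can
inflate errors even when they pass the shape filters. The 50-px area
threshold is kept in pixels with the pixel size recorded alongside, since
it is defined at the standard 0.05 μm/px sampling.

## Morphometry

For one fiber the reference region is the union of its axon and myelin
pixels, so AVF + MVF = 1 exactly and

    g = sqrt(1 / (1 + MVF/AVF)) = sqrt(|axon| / |region|),

which equals the classical `r/R` for an ideal annulus. This region choice
resolves the ambiguity of "total area of the region" in favour of the
definition that makes the area-based and diameter-based g coincide.
Diameters are area-equivalent circle diameters (`2 sqrt(area/pi)` times
the pixel size) — robust to boundary pixelation compared with Feret or
axis lengths — and myelin thickness is half the difference of the fiber
and axon equivalent diameters. A fiber with no assigned myelin gets
MVF = 0, g = 1, thickness 0 and an `unmyelinated` flag rather than an
error; exclusion is the selection stage's decision. Aggregation reports
mean and sample SD (n−1); a single row reports SD 0 with a flag.

On noise-free circular phantoms (r 8–20 px, outer radius r/0.6) the
pipeline recovers every fiber's g-ratio within 2% of r/R and the
population mean within 0.01 — pixelation at the smallest radii is the
dominant error, and it shrinks with supersampling (asserted in the tests).

## Evaluation

Dice = 2|A∩B|/(|A|+|B|) per one-vs-rest class, with empty-vs-empty
defined as 1.0 (the 0/0 case); pixel accuracy is (TP+TN)/n on the same
binarization, matching per-class reporting. `evaluate_selected`
additionally restricts both metrics to the support of the selected fibers
plus the ground-truth foreground inside their bounding boxes, so errors
concentrated in rejected fibers no longer count — the mechanism by which
selection improves the reported scores.

## Statistics

* **ICC(3,1)** (two-way mixed effects, single rating, consistency):
  `(MS_rows − MS_err) / (MS_rows + (k−1) MS_err)` from the two-way ANOVA
  decomposition; CI by the exact F method; p from
  `F = MS_rows/MS_err` on `(n−1, (n−1)(k−1))` df. Bands: < 0.50 poor,
  0.50–0.75 fair, 0.75–0.90 good, ≥ 0.90 excellent; both interior
  cut-offs are closed on the right (0.50 is "fair", 0.90 is "excellent"),
  a documented resolution of the prose ambiguity. The implementation is
  checked to 1e-10 against an explicit mean-squares brute force and
  against `pingouin`'s ICC(C,1). Zero-variance tables return a degenerate
  flag instead of a number.
* **Bland–Altman**: bias = mean(a−b), limits of agreement bias ± 1.96 sd
  (asserted to 1e-9 by construction); proportional bias from regressing
  the differences on the pair means, slope p reported at the 5% level.
* **Paired comparison**: Shapiro–Wilk on the differences gates between the
  Wilcoxon signed-rank test (normality rejected at 5%) and the paired t
  test; both p-values are always reported. Wilcoxon drops zero
  differences, uses the exact null distribution up to n = 25 when ranks
  are untied (verified against full 2^n sign enumeration at n = 8), and
  the normal approximation with tie and continuity correction above. The
  gated procedure's overall type-I rate is checked to stay near 5% under
  null simulations. All-zero differences return a degenerate flag.
* **One-way ANOVA** for parallel sections, fixed effects; identical groups
  give F = 0, p = 1, and the null p-distribution is checked for
  uniformity over seeded repeats.

Group comparison between independent runs (`compare_groups`) uses
Mann–Whitney U (or Welch's t when both groups pass normality) for two
runs, since fibers from different sections cannot be paired, and one-way
ANOVA for three or more. No multiple-testing correction is applied.

## Problem sizes and numerical choices

The documented experiments use phantom sizes chosen for a single-CPU
numpy workflow: 1024² scenes with 50 fibers for geometric recovery, 512²
with 23 fibers for selection exactness, 256² patches (10 train / 5
validation) for the reduced training run, and 200 resampled repeats for
the ANOVA calibration. Probability normalization tolerance is 1e-5;
morphometric identities (AVF+MVF = 1, g from the volume-fraction formula)
are enforced to 1e-12; metric and ICC oracle equivalences hold to 1e-12
and 1e-10. Ties in the threshold rule, watershed assignment, argmax and
band edges are all resolved by the documented deterministic conventions
above.

## Known limitations

* Phantom appearance is stylized; network results on phantoms say nothing
  quantitative about real sections.
* The diameter/thickness estimators (area-equivalent circle) are one
  defensible choice among several; per-ray or axis-based estimators would
  give slightly different thickness on elongated fibers. The estimator is
  isolated behind the morphometry module so alternatives can be added.
* Merged axons are not split; touching fibers are resolved only at the
  myelin-assignment level.
* The network trainer is CPU-bound pure numpy: suitable for the reduced
  configuration and correctness work, not for full-scale training runs.
* Whole-slide formats are out of scope; inputs are plain TIFF/PNG patches.
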