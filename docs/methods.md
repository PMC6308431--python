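# Methods

## The grading pipeline

`blastograde` grades single-embryo brightfield images of bovine
blastocysts on the IETS quality scale restricted to viable embryos
(1 excellent/good, 2 fair, 3 poor). The pipeline has five stages:

1. **Standardization.** Any input (BMP/JPG/PNG, RGB or grayscale, any
   resolution) is converted to 8-bit grayscale (BT.601 luminance
   weights, rounded half-up), resized to 640x480 preserving aspect
   ratio (center-padded with the median border intensity; the pad mask
   is kept so later stages can ignore it), and contrast-stretched so
   that 1% of pixels saturate (0.5% at each tail). The stretch is
   monotone and idempotent up to one intensity level; a constant image
   passes through unchanged.
2. **Segmentation.** The Sobel gradient magnitude is min-max rescaled
   to [0, 255] and thresholded at 128 (`>=` keeps the boundary value).
   A circular Hough transform searches radii 100–150 px and then
   150–200 px (grid step 2 px); the stronger of the two stage winners
   is kept, ties going to the larger radius, and detections below a
   strength floor of 0.25 are discarded. Around the detected circle
   three regions are cut: ER (radius + 5 px, the embryo including the
   zona pellucida), RR (radius − 40 px, inner cell mass + blastocoel)
   and TE (ER minus RR, the trophectoderm annulus).
3. **Features.** 36 variables per image: for each region, five
   grey-level co-occurrence statistics (contrast, correlation, energy,
   homogeneity, entropy; 8 intensity levels, distance 1, averaged over
   the four axis/diagonal directions, pairs counted only when both
   pixels are in-mask) plus mean, standard deviation and
   above-background area fraction; and twelve whole-embryo variables
   (region radii and areas, intensity ratios, detection strength,
   gradient energy, border contrast, centroid offset, an eccentricity
   proxy and the ER histogram entropy). Iterated variance-inflation
   pruning then removes, one per iteration, the variable with the
   largest VIF above 10 until all survive, and reports the removal
   trail (a 12-removal run reports 13 iterations, counting the final
   confirmation pass).
4. **Grading.** Three feedforward networks (24 inputs, 3 softmax-scored
   outputs) trained by full-batch backpropagation with early stopping
   vote by mode; a three-way disagreement falls back to the median
   ordinal grade. Each network's architecture is a 9-gene chromosome
   (three hidden-layer sizes, three hidden transfer functions, output
   transfer function, trainer, number of active layers) optimised by a
   generational genetic algorithm.
5. **Rescue (small images).** Smartphone-through-ocular captures put
   the embryo far below the main search window (radius ~10–75 px vs
   100–200). Such images are histogram-equalized, binarized, scanned
   with a variable-range Hough sweep (windows 8–20, 20–45, 45–75,
   75–100 px; watershed-of-distance-transform fallback), cropped to 3x
   the detected radius, and expanded by bicubic interpolation until the
   embryo radius reaches 150 px — the midpoint of the main window —
   then re-enter stage 2 on a standard 640x480 canvas.

## Detection strength and the acceptance floor

The Hough accumulator proposes, for each candidate radius, the best
center; the candidate's *strength* is its arc coverage: edge pixels
within ±1.5 px of the circumference are binned by angle (bins of ~3 px
of arc) and strength is the fraction of occupied bins. A complete
circumference scores ~1, a half-erased one ~0.5, and dense clutter that
merely crosses the annulus scores low. This makes the acceptance floor
(0.25 = a quarter of the circumference supported) meaningful across
image content, which the raw accumulator peak is not: vote spreading
caps a perfect circle near 0.32 while extreme order statistics over
~3x10^5 candidate centers push pure-noise peaks above any usable
constant. Coverage keeps a second useful property the accumulator
lacks: embryos with true radius below 100 px leave only short arcs
inside the main search annuli and are *never* accepted, which is
precisely the failure mode the rescue path exists to fix.

## Rescue-path binarization

The rescue path must isolate objects covering anywhere from ~3% down
to ~0.2% of the frame. After equalization and a 2% contrast stretch the
image is smoothed (Gaussian, sigma 1.5) and thresholded with the
triangle rule rather than Otsu: Otsu maximises between-class variance
and, when the object class is ≪1% of pixels, simply splits the
background. Foreground is the minority class; connected components
under 100 px (below a radius-8 object, the sweep's floor) are removed,
and a "foreground" exceeding 25% of the frame — impossible for an
embryo within the sweep's 100 px radius cap — is treated as
structureless clutter and discarded. These guards are what make a
pure-noise input return `not_found` instead of a spurious detection.
The Hough sweep votes on the boundary of the binary foreground, not the
filled blobs.

## Bicubic expansion

Each output sample evaluates the unique bicubic surface
f(x, y) = Σ_{i,j≤3} a_ij x^i y^j through its 4x4 source neighbourhood.
The implementation uses separable cubic Lagrange weights on nodes
{−1, 0, 1, 2}, which is algebraically identical to fitting the 16
coefficients per patch (`BicubicPatch` exposes that explicit form and
the tests verify both paths agree). Interpolation is therefore *exact*
(≤1e-6) for source surfaces polynomial of degree ≤3 in each coordinate
— the property that distinguishes it from cubic-convolution kernels,
which only reproduce quadratics. Borders use clamped replication;
output is clipped to [0, 255]; upscaling is capped at 20x.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| working resolution | 640x480 | px | lowest standard resolution carrying enough texture |
| saturation fraction | 0.01 | — | 1% total, split 0.5%/0.5% low/high |
| gradient threshold | 128 | intensity | fixed threshold on the min-max-rescaled magnitude |
| main Hough windows | [100,150], (150,200] | px | initial vs expanded blastocysts |
| strength floor | 0.25 | coverage | a quarter of the circumference must be supported |
| ER / RR offsets | +5 / −40 | px | include zona pellucida / exclude trophectoderm |
| GLCM levels / distance | 8 / 1 | — / px | bin width 32; four angles averaged |
| VIF threshold | 10 | — | conventional collinearity cut-off |
| split fractions | 70/15/15 | % | train / validation / test, stratified by grade |
| GA rates | crossover 0.8, mutation 0.05/gene, migration 0.05, elitism 2 | — | tournament size 3 |
| rescue target radius | 150 | px | midpoint of the main search window |
| crop factor | 3x radius | — | keeps zona + margin around the embryo |

All are exposed as module constants or config/CLI options.

## The synthetic generator

No study images are deposited, so `blastograde.synthetic` renders
ground-truthed stand-ins: a flat (or gradient) noisy background, a
blastocoel disk, a textured trophectoderm annulus (thickness 40 px
scaled by radius/150), a bright zona-pellucida ring (half-thickness
3 px — kept constant so the ring's edge band does not bias the
recovered radius), and an off-center inner-cell-mass blob. Grade
degrades morphology: ring erasure 0/15/35%, boundary asymmetry
0/0.02/0.06 (sinusoidal radius modulation), vacuole speckles 0/3/9,
chosen so that grade 1–2 renders segment fully and grade 3 typically
partially. Radius ranges emulate the three acquisition regimes —
microscope 100–200 px (~24% mean area fraction), smartphone Dataset-1
45–75 px (~3%), smartphone Dataset-2 10–20 px (~0.2%). Smartphone
regimes render at 1280x960 and block-average down, emulating optical
capture through an ocular. Gaussian pixel noise defaults to sd 5.

The renders are geometric caricatures: they contain no blastomere
texture, debris, illumination vignetting, focus blur, or zona cracking.
Passing detection/rescue tests on them demonstrates the geometry and
plumbing of the method — that the two windows, offsets, coverage floor
and rescaling interact as designed — not clinical-grade performance on
real micrographs.

`generate_feature_dataset` sidesteps rendering entirely for
training-path tests: three 24-dimensional Gaussian grade clusters
(means `separation`·sigma apart along random orthogonal directions;
within-class covariance with blocks of four at correlation 0.35, low
enough that every base column's VIF stays well under 10).
`extend_with_collinear` appends 12 columns, each the mean of a
standardized, sign-aligned, *disjoint* pair of base columns plus noise
(sd 0.01): predicting an appended column from the rest leaves only its
own noise as residual while predicting either source leaves twice that,
so the appended columns provably carry the largest VIFs and the greedy
pruner removes exactly those twelve (12 removals + 1 confirmation = 13
iterations, matching the 36 → 24 reduction).

## Numerical choices and degenerate inputs

- Coordinates are 0-based (row, col); disks are inclusive
  (distance ≤ radius). Binarization keeps the boundary value (≥128).
- VIF ties (equal maxima, e.g. exact duplicates) remove the earlier
  column in schema order; exact collinearity (R² ≥ 1 − 1e-12) returns
  +inf.
- GLCM correlation of a single-level region is defined as 1; entropy
  uses 0·log 0 = 0.
- Prediction ties break toward the worse (higher) grade — the
  conservative call for an embryo transfer decision.
- Rprop is the iRprop− variant (step x1.2 on sign agreement, x0.5 and
  no step on sign flip, steps clipped to [1e-8, 1]).
- Constant images: standardization and equalization are identity;
  binarization returns all-false.
- A detected circle with radius ≤ 40 px cannot host the −40 px reduced
  region and raises a degenerate-region error (the pipeline reports
  status `none` instead of propagating).
- Status without ground truth: `full` iff ≥50% of ER pixels exceed the
  background (median intensity outside ER). With synthetic ground
  truth: IoU of detected vs true ER disks, `full` ≥ 0.90, `partial` ≥
  0.30. The comparison is ER-to-ER because comparing the detected ER
  against the bare embryo disk would bound IoU below 0.94 even for a
  perfect detection.

## Problem sizes

Tests and the acceptance script run at desk scale on one CPU: 50 random
clean circumferences for radius recovery, 12 Dataset-1-regime renders
for the rescue property, 150x36 matrices for collinearity pruning, and
a GA of population 20 over 5 generations (memoized fitness; ~70 network
trainings) on 300 surrogate feature vectors. The full suite runs in
about two minutes; the acceptance script in about one.

## Known limitations

- The grading networks are only as meaningful as their training data;
  the package ships no pretrained weights and the original hundreds-of-
  image training corpus is not public. On synthetic surrogates the
  ensemble is near-perfect by construction; no claim transfers to real
  embryo images without retraining.
- The renderer's simplifications (above) mean segmentation performance
  percentages measured here cannot be compared numerically with values
  measured on real micrographs.
- Only one embryo per image is supported; the Hough search returns the
  single best circle.
- The Dataset-2 regime (radius ~15 px) survives the rescue path but,
  after ~10x magnification, its zona ring is several pixels wide and
  the re-detected radius lands on the ring's outer edge, so such images
  typically classify as `partial` rather than `full` — the small-image
  regime remains intrinsically harder, as the original group-wise
  segmentation rates suggest.
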