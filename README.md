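# blastograde

Automated grading of bovine blastocyst brightfield images, including
small smartphone-through-the-ocular captures.

In vitro embryo production labs grade blastocysts visually on the IETS
scale (1 excellent/good, 2 fair, 3 poor), which is subjective and
requires an inverted microscope. `blastograde` implements an objective
image pipeline for single-embryo images:

1. **standardize** — 8-bit grayscale, 640x480, 1% saturation stretch;
2. **segment** — Sobel gradient → threshold 128 → two-stage circular
   Hough transform (radii 100–150 then 150–200 px, strongest circle
   wins); the detected circle is expanded +5 px (**ER**, embryo with
   zona pellucida), shrunk −40 px (**RR**, inner cell mass +
   blastocoel), and differenced (**TE**, trophectoderm annulus);
3. **features** — 36 texture/geometry variables (masked grey-level
   co-occurrence statistics per region + shape/intensity variables),
   pruned by iterated variance-inflation-factor elimination
   (drop the worst VIF > 10, refit, repeat; 36 → 24 in the reference
   configuration);
4. **grade** — the mode of three independent feedforward ANNs trained
   by backpropagation on the reduced features; network architectures
   (layer sizes, transfer functions, trainer — a 9-gene chromosome)
   are found by a genetic algorithm;
5. **rescale** (the rescue path) — embryos photographed through a
   stereomicroscope ocular with a phone camera occupy ~0.2–3% of the
   frame and defeat the main Hough window. A variable-range Hough
   sweep (8–100 px; watershed fallback) finds the small embryo, the
   image is cropped around it and expanded by bicubic interpolation
   f(x,y) = Σᵢⱼ aᵢⱼ xⁱ yʲ (i, j ≤ 3, exact on cubic surfaces) until
   the embryo reaches radius 150 px, and segmentation is retried.

Because no study images are public, `blastograde.synthetic` renders
ground-truthed blastocyst stand-ins in all three acquisition regimes
and generates labelled feature datasets, so every stage is testable
offline.

## Worked example

Render a small smartphone-regime embryo, rescue it, and segment:

```sh
$ blastograde --seed 3 synth fxsp --regime smartphone_d1 --n-per-grade 1
wrote fxsp/manifest.csv
$ blastograde rescale fxsp/embryo_000_smartphone_d1_g1.png fxsp/expanded.png
found_by=hough_variable_range scale=2.63 wrote fxsp/expanded.png
$ blastograde segment fxsp/expanded.png --out-prefix fxsp/seg
status=full circle=240.0,322.0,148.0,1.0000,stage1_100_150
```

The small embryo (true radius ~57 px, invisible to the main 100–200 px
search) was found by the variable-range sweep, expanded 2.63x, and then
fully segmented: the re-detected circle sits at (240, 322) with radius
148 px and arc coverage 1.0 (a complete circumference). Direct
segmentation of the same image reports `status=none`.

Frequency testing of segmentation counts (groups as CSV rows):

```sh
$ printf 'group,seg,not\nI,11,7\nII,14,4\n' > counts.csv
$ blastograde stats counts.csv --method fisher
{"method": "fisher_exact_2x2", "statistic": null, "df": null,
 "p_value": 0.47052280311457173, "significant_at_5pct": false}
```

Train and apply an ensemble from a labelled feature table:

```sh
$ blastograde --seed 2 train features.csv --out-prefix m
model 1: test accuracy 1.000 -> m_1.json
...
$ blastograde --seed 2 batch manifest.csv m_1.json m_2.json m_3.json
segmentation counts: {'full': 3, 'partial': 0, 'none': 0}
```

The library mirrors the CLI one-to-one (`blastograde.standardize`,
`segment`, `extract_features`, `vif_prune`, `train_ann`,
`ensemble_predict`, `evolve`, `rescale_image`, `grade_image`, ...); see
`docs/methods.md` for the model details, parameter table and
limitations.

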