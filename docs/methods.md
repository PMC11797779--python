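# Methods

## Problem and pipeline

Radiographic periodontitis assessment reduces to one ratio per tooth: the
maximum alveolar bone-loss (BL) height between the cemento-enamel junction
(CEJ) and the bone crest, divided by the root length (CEJ center to root
apex). The pipeline estimates that ratio from a periapical radiograph in
four stages — BL segmentation, apex detection, landmark geometry, and
rule-based staging/grading — and ships the complete metric suite used to
evaluate each stage.

## Synthetic data: what it emulates, and what it does not

Clinical periapical radiographs of periodontitis patients are private, so
the package generates its own. Each synthetic case preserves the geometric
relations the pipeline measures, on a 160×320 raster at 0.1 mm/px:

- 1–4 teeth per image, each a filled trapezoid silhouette (bright crown
  tapering to the root apex) on a bone-gray background;
- a solid dark band from the CEJ line toward the bone crest is both the
  visual BL area and the mask's single connected component per tooth. The
  band has odd width and is centered on the CEJ column, and its height is
  an exact pixel count, so on a noiseless rendering the measurement chain
  recovers the CEJ center, BL height and BL% to floating-point precision;
- apexes are Gaussian bright blobs (σ = 2 px, peak 255) at known integer
  coordinates, annotated with 9×9 px YOLO-style boxes;
- additive Gaussian sensor noise (default sd 8 gray levels, clipped to
  [0, 255]).

Default generation parameters: root lengths uniform in 65–115 px
(6.5–11.5 mm), BL fractions uniform in 0.05–0.60 of root length (mean BL%
32.5, spanning all three stages), patient ages uniform in 20–70 years
(spanning all three grades), three teeth per image. Identical seeds give
byte-identical images and ground truth; every case id is generated from an
independent seed stream, so datasets are stable under reordering.

What the generator does **not** emulate: anatomical texture (trabecular
bone, lamina dura, enamel caps), projection distortion, furcation-shaped
defects, overlapping teeth, or variable pixel calibration. Passing tests
therefore demonstrate the *correctness of the computational chain* —
geometry, bookkeeping, statistics, and the trainability of the segmenter —
not clinical-grade performance on real radiographs.

## Preprocessing and augmentation

Images are resized to 160×320 (bilinear), histogram-equalized with the
classic CDF remap `(cdf(v) − cdf_min)/(N − cdf_min)` (a constant image is
left unchanged), and scaled to [0, 1]. Masks use nearest-neighbour
resampling and are re-binarized after every geometric transform.

The dataset is split 80:10:10 by case id *before* augmentation;
validation/test sizes are `round(ratio·n)` with the remainder to train.
Each train and validation case then gains exactly one augmented copy —
horizontal flip and/or a rotation drawn from ±{5, 10, 15}° — so 1,000
cases yield 1,600 training and 200 validation items while the 100 test
cases stay untouched. Augmenting the validation set alongside training is
unusual but reproduces the reference data pipeline this package follows;
the split/augment bookkeeping is asserted by id so copies cannot leak
across splits. The detection branch skips equalization (it only resizes
and rescales): global equalization flattens the intensity ranking that
separates the small bright apex blobs from enamel.

## Segmentation model

The reference U-Net: four encoder blocks (64/128/256/528 filters), a
1,024-filter bridge, four decoder blocks (512/256/128/64), trained with
Dice loss (ε = 1e-6), Adam (lr 1e-4), batch 8, 15 epochs. The 528 in the
third encoder position is kept verbatim as the reference configuration;
any filter list (e.g. the conventional 512) can be passed instead. Blocks
are two (3×3 convolution → batch normalization → ReLU) stages; 2×2
max-pooling, 2×2 transposed-convolution upsampling, channel-concatenated
skips, and a 1×1 convolution + sigmoid head. Batch normalization is an
implementation choice beyond the minimal block description: without it,
the smallest configurations (4 first-layer filters) fall into dead-ReLU
basins under the Dice loss for some initializations, while with it the
desk-scale model trains reliably across seeds.

The engine is pure NumPy (im2col convolutions, hand-written backward
passes, float32) and single-threaded; it is verified against central
finite differences (directional derivative, agreement to ~1e-4 at
ε = 3e-5). Probability maps are thresholded at 0.5, with probability
exactly 0.5 counted as foreground.

Desk-scale configuration used throughout the tests: filters 4/8/16/32,
bridge 64, lr 1e-2 (small BN networks tolerate and benefit from the larger
step), 5 epochs on 200 synthetic 64×128 images — about half a minute on
one CPU, reaching held-out Dice ≥ 0.99 across seeds. The reference
full-size configuration is exercised for construction and parameter
accounting only; no pretrained weights are shipped.

## Apex detection

The detector contract is YOLO-style text labels, so any external detector
can feed the pipeline. The built-in reference detector targets the
generator's rendering: light Gaussian smoothing (σ = 1, a matched filter
for the σ = 2 blobs), local maxima above intensity 0.8 (between the
brightest extended structure, enamel at ~0.75, and the smoothed blob peak
at ~0.89), and a 4 px non-maximum-suppression radius. Confidence is the
smoothed peak intensity. On noiseless renderings it localizes every apex
within 2 px; at the default noise it still recovers ≈99% mAP against the
9×9 ground-truth boxes.

## Geometry

- Connected components: 8-connectivity; components under 20 px² are
  treated as speckle (the threshold is configurable).
- Maximum BL height = bounding-box height (vertical extent) of the region,
  not a path length along the root.
- CEJ center: bbox midpoint of the border facing the crown; the x midpoint
  floors the half pixel, i.e. `x = (x_min + x_max) // 2`.
- Root length: Euclidean distance CEJ→apex in pixels; BL% is clipped to
  [0, 100]; a zero root length (apex coincides with CEJ) is an error.
- The 2 mm physiological allowance is applied as a *retention filter*
  (regions with BL height ≤ 2 mm at the configured mm/px are dropped), not
  subtracted from BL%, because the staging thresholds operate on the raw
  BL/root ratio.
- Region↔apex association pairs each region with the apex minimizing the
  horizontal distance to the region's bbox x-midpoint (ties by Euclidean
  distance, then by smaller apex x); unpaired items are reported rather
  than guessed.

## Staging and grading

Stage from worst-tooth BL%: I < 15, II 15–33 (both endpoints inclusive),
III/IV > 33. Stages III and IV are merged because tooth-loss and
complexity criteria are not observable in a single image. Grade from
BL%/age: A < 0.25, B 0.25–1 (both endpoints inclusive), C > 1. Patients
with no retained tooth measurement get an explicit "no assessable BL"
result, never a stage. Thresholds live in one `StageGradeThresholds`
object and are overridable.

## Metrics

Conventions, chosen once and used everywhere:

- 0/0 → 0 for precision/recall/F1 (a never-predicted class scores 0.0);
- per-class "accuracy" in classification reports is the class recall,
  matching how per-category staging tables are published; overall
  precision/recall/F1 are support-weighted;
- ROC-AUC is the rank statistic (ties 0.5), computed on pooled pixels for
  segmentation;
- ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the
  two-way ANOVA table, F = MSR/MSE, with Shrout–Fleiss F-based 95% bounds
  (Satterthwaite degrees of freedom). Exactly identical raters short-cut
  to ICC = 1 to avoid floating-point cancellation in the sums of squares;
  zero total variance additionally warns. Cross-checked against
  `pingouin.intraclass_corr` in the test suite;
- average precision uses all-points interpolation (area under the monotone
  precision envelope); mAP averages IoU thresholds 0.50:0.05:0.95;
  matching is greedy in confidence order, each truth matched at most once.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.Generator` seeded from
  explicit seed sequences; identical seeds give byte-identical outputs,
  including trained weights (single-threaded float32 arithmetic).
- Dice loss ε = 1e-6 guards empty masks; a non-finite loss aborts training
  with the epoch/batch in the message.
- Training keeps the weights (and batch-norm running statistics) of the
  best-validation-loss epoch.
- Masks read from PNG are thresholded at 128 with a warning if not
  already binary; label files reject out-of-range normalized values with
  the line number.

## Problem sizes used by the tests and the acceptance script

Geometry recovery uses 200 noiseless three-tooth cases (600 teeth);
learning sanity trains the desk-scale U-Net on 200 cases at 64×128
(160/20/20 split); oracle-equivalence batteries use 50 randomized
instances per statistic; detector mAP uses 50 noisy cases; the
BL%-agreement ICC uses 100 noisy cases. These sizes exercise every code
path at comfortable desk scale.

## Known limitations

- The synthetic image model is geometric, not photometric; segmentation
  performance numbers on it say nothing about real radiographs.
- One BL region per tooth; furcation defects and multi-root geometry are
  out of scope.
- No tooth numbering or mesial/distal site attribution; association is
  purely horizontal-geometric.
- mm calibration is an explicit configuration (default 0.1 mm/px), not
  read from image metadata.
- The staging rules use only radiographic BL%; clinical attachment level,
  tooth loss and complexity factors of the full 2017 workshop scheme are
  not modelled.
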