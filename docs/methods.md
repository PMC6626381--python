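# Methods

## The estimation problem

The heading date of a paddy-rice crop — operationally, the date on which
50% of the panicles have exserted from the leaf sheath — is a key
phenological trait for breeders and agronomists. Field scoring of it is
subjective and laborious. `headingdate` implements an image-based
estimator: a fixed camera photographs the canopy several times a day
through the flowering window; each image is scanned with a sliding window;
a binary CNN classifies the patch under every window position as *flower*
or *non-flower*; the number of positive windows per image is used as a
count proxy for the number of flowering panicles; and the heading date is
read off the cumulative count curve at its 50% crossing.

The method deliberately does **not** localize panicles. For a fixed window
size, the count of flowering windows is proportional to the number of
flowering panicles present, and proportionality is all the 50% rule needs
(the crossing point of a cumulative curve is invariant to positive
rescaling of the counts — a property the test suite checks directly).

## Pipeline stages and their parameters

### Sliding-window detection

Window positions are `(i·stride, j·stride)` with every whole window inside
the image; border remainder strips are dropped, not padded. No merging or
non-maximum suppression is applied: counts are *window* counts. Shipped
per-dataset defaults for the real five-sequence acquisition (window w×h,
stride, px): Kinmaze 140×140/140; Kamenoo 160×160/140; Koshihikari-1/2/3
160×160/150. Note the Kamenoo stride is smaller than its window, so
windows overlap and one panicle can be counted twice; counts remain
proportional, which is sufficient for the 50% rule. The decision threshold
on the sigmoid output is 0.5 (configurable per `WindowConfig`).

### Patch classifier

The default backbone is a small scratch CNN: four 3×3 same-padding
convolution blocks (8/16/32/32 channels, ReLU, 2×2 max-pool after the
first three), global average pooling, and a single-logit dense head;
`predict_prob` applies the sigmoid. Training is binary cross-entropy under
the standard protocol: stochastic gradient descent, learning rate 0.001,
momentum 0.9, 3 epochs. Batch size (32) and the seeded per-epoch shuffle
are implementation choices the protocol leaves open. An
ImageNet-pretrained ResNet-50 with the same replaced sigmoid head is
available behind the same interface when torch is installed; nothing in
the package or its tests requires it.

Two numerical choices matter for training this head from scratch in only
3 epochs:

* **Input standardization.** Patches are mapped to zero mean and roughly
  unit variance (`(x − 127.5)/63.75`). With inputs scaled an order of
  magnitude smaller, the protocol's gradient magnitudes are too small to
  move the logits usefully within ~100 SGD steps.
* **Zero-initialized head.** The dense head starts at exactly zero, so the
  untrained model predicts 0.5 for everything. A randomly initialized head
  gives the logit distribution a seed-dependent offset that the short
  protocol cannot cancel, which silently breaks the fixed 0.5 decision
  threshold; with a zero head and balanced classes, the decision boundary
  grows symmetrically between the class means.

Determinism: the training seed fixes weight initialization and the
shuffle; inference processes one sample at a time internally (identical
GEMM shapes per sample), so predictions are bit-identical regardless of
batch composition or storage order. Reproducibility is asserted on
predictions, not on raw weights.

### Training-set construction

Positive patches are the annotated tight flowering-region boxes
themselves, resized bilinearly to the classifier input size (224 px by
default); negatives are window-sized crops sampled uniformly from the same
images with zero pixel overlap with any ground-truth box (the strictest
reading of "background", avoiding label noise). The negative window uses
the dataset's detection window dimensions. Validation images are built by
picking, per series, 15 images spread equally over three time-of-day slots
(8–9 a.m., 11 a.m.–12 p.m., 3–4 p.m.) and taking one random fixed-size
crop from each; clipped ground-truth boxes are kept only if at least half
their area survives (symmetric with the IR threshold below).

### Detection evaluation

Because predictions are fixed-size windows and ground truth is tight
boxes, IoU would penalise every correct detection. The package scores a
prediction with the asymmetric **Intersection Ratio**,

    IR = (area of overlap) / (area of the predicted box),

and calls a prediction positive iff its best IR over all ground-truth
boxes is ≥ 0.5. Matching is one-to-many: several positive predictions may
cover one ground-truth box and all count as true positives (per-box
positivity does not dedupe, and window grids naturally overlap large
panicles). Recall is the fraction of ground-truth boxes covered by at
least one positive prediction — the only denominator consistent with
per-box positivity; this definition is this package's choice.

### Heading-date estimation

Per-image counts are accumulated in timestamp order; the estimate is the
calendar day of the first image whose running total reaches half the
season total (≥ rule, first crossing, no interpolation — estimates are
whole days). Signed error versus a field observation is
`estimated − observed` in whole days; the five real sequences' field-book
dates ship as a reference fixture (inputs, never recomputed). Day indices
are whole days elapsed since transplanting (transplanting = day 0); the
field study's printed day labels follow a different internal numbering and
are retained verbatim in the fixture without being mixed into computation.

### Grad-CAM

For a patch classified as flower, the gradient of the flower logit is
taken with respect to each feature map of a chosen convolutional layer
(default: the last spatial layer); global average pooling of the gradient
gives one weight per map; the ReLU of the weighted sum of maps, upsampled
bilinearly to patch size and divided by its maximum, is the heatmap. An
identically zero raw map stays zero. Max normalization (not min–max) is
used because the raw map is already nonnegative after the ReLU; both the
normalization and the upsampling are this package's choices.

## The synthetic field study

Real field imagery cannot ship with the package, so every end-to-end
claim is exercised on synthetic seasons with analytically known truth.

**What the generator emulates.** Rice is transplanted on a regular grid of
hills, so panicle sprites are placed on a planting-grid lattice (80 px
pitch by default, at most one new panicle per cell per day, placement
jittered within the cell). A sprite is a bright, randomly oriented,
squarish superellipse blob (major axis 56–76 px, aspect 0.55–0.85) whose
channel values occupy a luminance band (≥ 205) disjoint from the darker
green canopy noise (clipped ≤ 165), mimicking the distinct brightness of
anthesis without modelling rice morphology. The emergence schedule (day →
newly flowering panicles) is an explicit input; the default season is a
10-day bell totalling 60 panicles around day 84 after a 2013-05-31
transplanting, with 3 images per day and a small global per-image
brightness jitter. Each panicle flowers for 1 day by default
(configurable). Identical parameters and seed give bit-identical pixels;
per-day and per-image sub-streams are derived from the seed so increasing
`images_per_day` never perturbs earlier slots.

**What it does not emulate.** Real canopies have occlusion, wind motion,
specular highlights, rain, exposure drift, and panicles whose appearance
changes within a day; sprite luminance is perfectly separable by
construction. Passing the end-to-end tests therefore demonstrates that the
pipeline machinery is correct — counts propagate, curves accumulate, the
50% rule lands on the right day, training is stable under the fixed
protocol — not that the classifier would reach field accuracy on real
imagery.

**Study scale.** The synthetic study uses 640×480 images, the 80 px
planting grid with a matched 80×80/stride-80 window, and a 64 px
classifier input; these sizes keep a complete 20-season study (generation,
training on 500+500 patches, detection over 600 images) in the low
minutes on one CPU while leaving every pipeline stage at full fidelity.
The paper-scale defaults (224 px input, 140–160 px windows) remain the
package defaults for real imagery.

**Known truth.** With the window grid matched to the planting grid, every
sprite lies inside exactly one window, so an oracle classifier that
thresholds the sprite luminance band yields per-image counts exactly equal
to panicle counts, and the estimated heading day equals the analytic 50%
emergence day — an exact, structural identity used to validate the
pipeline independently of learning. The trained CNN replaces the oracle in
the second arm of the study and is held to a mean absolute error of at
most 1 day over 20 independent seasons.

**Validation-crop metrics.** The detection-metrics study takes random
320×320 crops, which deliberately break grid alignment. There the study
window is scanned with stride 20 (overlapping windows, as in the shipped
Kamenoo configuration): with the aligned stride of 80 almost no window
captures enough of a boundary-split sprite to clear IR ≥ 0.5. Even so,
recall is intrinsically limited: a compact sprite whose tight box is less
than half the window area can never be "covered" under the IR rule by a
window-sized prediction. The reported precision/recall on synthetic crops
should be read as an exercise of the evaluation machinery, not as a
forecast of field performance.

## Degenerate inputs and tie-breaks

* Boxes are 0-based half-open; zero-area boxes are rejected at
  construction, and 1-based or inclusive-end dialects must be converted at
  the I/O boundary.
* Two images in the same minute are rejected, not silently reordered.
* The 50% crossing uses ≥ at the first qualifying timestamp; an all-zero
  count curve is an error ("no flowering detected"), as is an empty
  emergence schedule.
* `detection_metrics` reports precision 0 (with a warning) when there are
  no predictions and recall 0 (with a warning) when there is no ground
  truth; F1 is 0 whenever precision + recall is 0.
* Pearson correlation refuses constant series, naming the offending one.
* Max-pool ties take the first (row-major) maximum; remainder rows/columns
  are dropped by pooling and by the window grid alike.

## Limitations

* The scratch CNN is intended for the synthetic study and desk-scale
  experiments; field-scale accuracy requires the pretrained backbone and
  real training data.
* Counts, not locations: the pipeline never merges adjacent windows, so
  region counts over-count large panicles at stride < window and
  under-count clustered panicles sharing a window. Both effects preserve
  the proportionality the heading-date rule relies on only approximately.
* Flowering duration is modelled in whole days; real anthesis spans hours
  within a day.
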