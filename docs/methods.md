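# Methods

## Class-selective relevance mapping

The saliency score of spatial element `(l, m)` of the deepest-conv feature
maps is the summed squared change of all `N` output-node scores when the
element is removed, `R(l, m) = Σ_c (S_c − S_c(l, m))²`, where removal
means zeroing all `K` channel activations at that location simultaneously.
The sum runs over every output node, which is what makes the map
class-*selective*: an element matters only if it moves the scores of the
classes apart.  The formula is implemented as written — a plain sum of
squared differences, with no 1/N normalization; the relative geometry of a
map (and everything downstream: thresholding, normalized fusion, box
extraction) is invariant to such a constant factor.

**Score definition.** `S_c` can be read before or after the softmax.  The
default is the pre-softmax logit: for a GAP + linear head the logit is
linear in each spatial element's pooled contribution, so removal has an
exact closed form and the map is independent of the softmax temperature.
The brute-force path also accepts `score_kind="probability"` for
post-softmax fidelity experiments; the two generally differ (the softmax
compresses large logit gaps), which is why the choice is explicit.

**Closed form.** With GAP normalizer `Z = u·v`, removing `(l, m)` changes
logit `c` by exactly `(1/Z) Σ_k W[k,c] f_k(l,m)` — every other element's
contribution and the bias cancel in the difference — giving
`R(l, m) = Σ_c ((1/Z) Σ_k W[k,c] f_k(l,m))²`.  The test suite verifies
elementwise agreement with literal removal at 1e−9 relative tolerance on
randomized instances; the brute force stays in the library both as the
oracle and as the only route for non-linear heads.

**Consequences of the definition.** The square makes the map sign-blind:
regions that argue *for* the normal class receive relevance too.  On a
two-class GAP head the two weight columns are nearly opposite after
training, so `R ≈ 2·(contribution to the abnormal logit)²` — peaks sit on
the most discriminative evidence in either direction.

## Map post-processing and ensemble fusion

Maps are upscaled to input-image size by bilinear interpolation (smooth,
standard for saliency display; non-negativity is preserved by clipping the
negligible interpolation undershoot).  Low scores are suppressed by
zeroing entries below a fraction (default 10%) of the map's own maximum;
the operation is idempotent.

Ensemble fusion averages maps from several models after making them
commensurable: upscale to a common size, divide each map by its own
maximum (architectures produce arbitrarily scaled score magnitudes;
without per-map normalization one model can dominate the mean by scale
alone — a raw-scale flag exists for fidelity), threshold each at 10% of
its own max, take the elementwise arithmetic mean over *all* maps (zero
maps count in the denominator), and display-threshold the mean at 10% of
its max.  The result is permutation invariant, bounded in [0, 1] under
normalization, idempotent on consensus, and supported only where at least
one thresholded input is nonzero.

## From heatmap to detections, and their evaluation

Boxes are 0-based and half-open, `[x_min, x_max) × [y_min, y_max)`, so
areas and intersections are exact integer-free arithmetic; the annotation
CSV convention `(x, y, width, height)` converts as `x_max = x + width`.

Detections are the 8-connected components of the display-thresholded map,
each reported as its tight extent with confidence = (maximum heatmap value
inside the box) × (classifier's abnormal-class probability).  Components
below a configurable `min_area` (default 0) are dropped.  Connected
components are the simplest reproducible proposal rule; it is deliberately
configurable because it is a design choice, not part of the relevance
definition.

Matching is greedy in descending confidence: a detection is a true
positive if its best-IoU unmatched ground-truth box reaches the IoU
threshold, consuming that box; otherwise a false positive — the standard
detection-benchmark protocol.  The precision–recall curve sweeps the
confidence threshold over all distinct detection confidences (ties
grouped), and AP is the all-point integral `Σ_i (r_i − r_{i−1}) p_i` with
`r_0 = 0` (no 11-point interpolation).  mAP averages AP over 10 IoU
thresholds evenly spaced on [0.1, 0.6], endpoints included.  The mean
per-image IoU pairs GT boxes and detections greedily by descending IoU
(each used once), counts unpaired GT boxes as 0, averages within an image
over GT boxes and then over images; images without GT boxes are excluded
by contract (the weak-supervision setting annotates boxes only for a
subset of abnormal images).

## Prediction ensembles

All strategies operate on per-model `n×2` probability tables (columns:
abnormal, normal).  Votes are cast at threshold 0.5; an even-count tie
resolves to *abnormal*, the conservative choice in a triage setting.
Weighted averaging is a convex combination (weights validated to sum
to 1); uniform weights recover the simple average.  Stacking trains a
one-hidden-layer network (hidden width 14, rectifier, softmax output;
scikit-learn `MLPClassifier`) on the concatenated base probabilities —
14 inputs for 7 models — by cross-entropy with early stopping on an
internal validation fraction, deterministic per seed.  Base learners are
frozen: their tables are pure inputs.  To avoid target leakage the
meta-learner should be fitted on held-out (validation-split) base
predictions; the CLI also allows fitting on the prediction tables
themselves, the literal single-stage protocol, when reproduction fidelity
matters more than leakage hygiene.

## Metric suite and Wilson intervals

Sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`, F measure
`2tp/(2tp+fp+fn)` and MCC `(tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn))`
are closed forms on the confusion counts (positive class = abnormal,
threshold 0.5).  Conventions for degenerate cells: rates over an empty
class are reported as missing (NaN); an MCC with a zero denominator is 0.
AUC is the trapezoidal area under the ROC swept over distinct score
values (ties merged).

The Wilson score interval uses `z` at quantile `1 − (1 − coverage)/2`;
reporting uses per-interval coverage √0.95 ≈ 0.9747 so that two
simultaneous two-sided intervals jointly cover at 95%.  Applying a
binomial-proportion interval to an AUC (with `n` = test-set size) is a
reporting convention, not a sampling model — AUC is not a binomial
proportion, and the resulting bands should be read as indicative.  The
implementation is the direct formula (the estimate need not be an integer
count divided by `n`); tests cross-check it against statsmodels'
`proportion_confint` at integer counts.

## Preprocessing

Given a binary lung mask, the crop box is the single tight box
accommodating *all* lung pixels (both fields in one box).  The crop is
rescaled to 256×256 without preserving aspect ratio — the fixed-size
rescale is taken literally.  Conditioning is a 3×3 median filter (reflect
border; border mode is otherwise unspecified and reflect avoids edge
bias), min–max rescale to [0, 1] (a constant image maps to zeros), and
standardization with **dataset-level** mean/std fitted on a training split
and persisted to JSON — per-image standardization would destroy the
"identical distribution" property across the split.

## Synthetic data generator

Each image (default 64×64, values in [0, 1]) is a brighter body field
(0.55) with two darker elliptical lung fields (0.25; centers/semi-axes
jittered by ~1% of image size per sample) plus smooth Gaussian-filtered
noise (σ ≈ size/16, amplitude 0.03).  An abnormal image adds 1–2 bright
Gaussian blobs (peak 0.8, σ uniform in [0.06, 0.09]·size, axis-wise)
centered well inside a randomly chosen lung ellipse; the ground-truth box
is the ±2σ rectangle (≈95% of blob mass) clipped to the lung-mask
bounding box, and boxes are placed non-overlapping.  Per-sample seeds are
spawned from the master seed via counter-based `SeedSequence` children, so
every output is a pure function of (seed, parameters).

The blob contrast and size were chosen once so that the desk-scale models
below can learn the task reliably in seconds; they are the generator's
fixed study conditions, not tuning knobs.  What the generator does *not*
emulate: rib/clavicle structure, exposure variation, pathology textures,
multi-scale opacities, label noise, or any anatomical correlation between
lesion position and lung shape.  Passing tests on this bed demonstrate
the correctness and the qualitative ensemble behavior of the pipeline,
not clinical-grade localization.

## Tiny CNN factory and desk-scale trainer

The model factory follows fixed architecture rules: three sections of
`depth` blocks each (3·depth blocks total); every block is a 5×5
depthwise-separable convolution (zero 'same' padding) + ReLU followed by
2×2 max-pooling; the kernel count starts at `ceil(image_size/√depth)` and
doubles per section; the head is GAP → dropout 0.5 → dense softmax over
two classes.  Two pragmatic adaptations for small images: pooling is
skipped once feature maps would drop below 4×4, so the deepest layer
always retains the spatial resolution relevance mapping needs; and batch
normalization is omitted — He-initialized frozen convolutions keep
activations at unit scale without it.

Training is deliberately desk-scale: the convolutional stage stays frozen
at its seeded He initialization (random convolutional features) and only
the GAP-linear softmax head is fitted — minibatch (size 8) Adam
(lr 0.05, β = 0.9/0.999) on the cross-entropy, with inverted dropout at
the architecture's 0.5 ratio on the pooled features, L2 weight decay 0.1,
features standardized by training-set statistics for conditioning (the
learned parameters are folded back to the raw feature scale, so the
exported (W, b) descriptor is exact), and early stopping on validation
loss (patience 5) keeping the best-validation parameters.  This trains in
milliseconds, is exactly reproducible, and suffices for the synthetic
task; it is *not* representation learning, which is why absolute
localization scores are far below what fully trained CNNs reach (see
limitations).  Demo models differ by convolution seed; at 64 px all use
depth 1, since deeper settings do not change the 8×8 deepest-layer
resolution but multiply cost.

Dataset splits default to 72/8/20 train/val/test by sample id (an 80/20
split with 10% of the training portion held out for validation).

## The end-to-end study

`crmloc.study.run_localization_study(seed)` runs the whole chain at its
default problem size — 200 samples, 3 models, ≤10 epochs, 64×64 images —
chosen so the complete study (simulation, feature extraction, training,
relevance mapping, evaluation) finishes in a few seconds on one CPU.  It
reports per-model held-out accuracy/AUC, per-model CRM localization
(mean IoU, mAP@[0.1 0.6]), the top-3 ensemble-CRM localization, and
voting/averaging prediction-ensemble metrics.  `scripts/acceptance.py` is
a thin wrapper that writes these quantities as JSON.

## Known limitations

- Absolute IoU/mAP at desk scale are small (~0.06 mean IoU): with random
  frozen features the relevance noise floor is high, so the 10%-of-max
  display threshold keeps most of the lung field and connected components
  merge into large boxes.  The meaningful desk-scale readout is the
  *relative* one — the ensemble map holds its own against the best
  individual map — not the absolute scores.
- The Wilson interval on AUC inherits the caveat above.
- `mean_image_iou` is one defensible reading of "averaging IoU over
  images" (greedy per-GT pairing); single-box-per-image or union-of-boxes
  conventions would give different absolute values.
- The CRM brute force costs one head evaluation per spatial element; for
  very large feature maps with non-linear heads it is O(u·v) forward
  passes (the closed form, where applicable, is one matrix product).
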