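# Methods

## The two-step screening model

An input image is screened in two stages. Stage 1 is a detector trained (or
constructed) only on the five atypical squamous Bethesda classes; it proposes
bounding boxes with a coarse class and a confidence, and its silence *is* the
NILM call — an image with zero detections above the confidence threshold is
negative for intraepithelial lesion or malignancy. Stage 2 crops every
surviving box plus a margin and re-grades it with a six-class ordinal
classifier; the refined class replaces the detector's coarse one. The stages
are trained separately (no end-to-end coupling), and stage 2 never changes
the number of detections, only their labels.

The image-level call is the maximum severity among refined boxes. Per-cluster
results are the primary output; the maximum rule is a deliberately
conservative aggregation for screening (an image is as suspicious as its
worst cluster) and is flagged as this package's own extension.

## Ordinal label smoothing

Targets for classifier training replace the one-hot vector for true class
`k` with `y_i = n^(−|k−i|)`, `n ≥ 1` integer (default 2). The weight is
exactly 1 at the truth and decays geometrically with ordinal distance, so the
cross-entropy `−Σ y_i log ŷ_i` rewards mass on neighbouring grades — the
co-occurrence structure of a continuous disease process. Design choices:

* **Unnormalized by default.** The literal weight vector sums to more than 1.
  A `normalized` flag rescales it to a distribution, which most loss
  frameworks expect; normalization rescales the per-sample loss by a constant
  depending only on `k` and does not move the minimizer.
* **Natural logarithm**; the base only rescales the loss.
* **Probability floor** `1e−12` before the log keeps the loss finite on
  near-zero inputs; non-positive probabilities are rejected outright.
* A loss-preference property that holds exactly: for `n ≥ 2`, swapping two
  predicted probabilities so that the class ordinally closer to the truth
  holds the larger one never increases the loss (rearrangement over the
  monotone weights). Note that *transferring* mass toward the truth can
  increase the loss when it empties an already-small distant probability —
  the log term diverges — so the property is stated and tested as a swap,
  not a transfer.

## Oversampling

Offline expansion is exactly 36× per image: a bank of **nine** photometric
filters crossed with the **four** flip states (identity, horizontal,
vertical, both). The identity of the nine filters is a configuration choice;
the default bank (brightness ±30, contrast ×1.3/×0.7, gamma 0.7/1.5,
Gaussian blur σ=1.5, unsharp sharpening, saturation ×1.5) mimics varying
light exposure, stain uptake and focus. Flips remap Darknet box annotations;
photometric filters leave them untouched. The unmodified original stays in
the base set and is not re-emitted.

Scale augmentation (enlarge by a factor in [1.0, 1.25], crop back to the
original size) and random erasing (p=0.5, area fraction 0.02–0.4, aspect
0.3–3.3 — the canonical defaults of those techniques) are applied only to
classifier training data. In this package's convex trainer, "online"
augmentation is realized by adding one rescaled-and-occluded variant per
training crop, so roughly half the effective training set carries an erased
rectangle.

## Synthetic scenes

The generator renders clusters of overlapping elliptical cells (pale
cytoplasm, dark nucleus) on a noisy pale background with optional debris.
Severity maps linearly to a nucleus-to-cytoplasm area-ratio ladder, 0.15
(NILM) to 0.75 (SCC), with nuclear-size variance and chromatin speckle
amplitude also increasing in class — chosen so that a monotone image
statistic separates the classes at desk scale. These are *learnability*
knobs, not claims about real cytology. Cluster centres follow a clustered
(parent + scatter) process; overlap is allowed by design, and a draw is
rejected only if a centre escapes the frame. NILM clusters are rendered but
produce no annotation box. Everything is a pure function of the spec,
including the seed.

What the synthetic data does **not** emulate: real staining variation,
out-of-focus depth, glandular morphology, three-dimensional cluster
structure, annotation disagreement, and class imbalance. Tests passing on
these scenes demonstrate the correctness and the qualitative behaviour of
the machinery, not clinical performance.

## Reference backends

* **BlobDetector** (deterministic, no training): pixels darker than the
  nucleus threshold (gray < 165) are dilated by a 6-px disk so the nuclei of
  one cluster merge into one connected component; components with < 40
  nuclear pixels are dropped. The nucleus/cytoplasm pixel ratio inside the
  component gates atypicality (default 0.47 — between the upper tail of
  rendered normal clusters and the bulk of the mildest atypical class) and
  maps to a coarse severity via fixed boundaries calibrated to the
  renderer's measured statistic; cell overlap saturates this statistic at
  high severity, so the top grades are intrinsically confusable in stage 1.
  Confidence is the (clipped) nuclear density itself.
* **OrdinalClassifier**: multinomial logistic regression over hand-crafted
  morphology features (nuclear/cytoplasm area fractions and their ratio,
  nuclear intensity mean and spread, local texture energy, a 6-bin gray
  histogram), standardized, with bias, L2 `1e−3`, trained by L-BFGS on the
  (optionally smoothed) cross-entropy. Zero-weight initialization makes an
  untrained model predict exactly uniform probabilities and makes training
  deterministic.

## The paired loss study

`compare_losses` generates, per seed, one shared train/test set of
*co-occurring-field crops*: the target cluster's annotation box (plus a 15%
margin) cut from a crowded 96×96 scene that also contains one or two
neighbouring clusters whose severity differs by one grade — neighbouring
grades co-occur on real slides because progression is continuous, and the
crop therefore mixes adjacent severities. Two classifiers are trained on
identical data (80 crops/class, augmented as above) differing only in the
target encoding (one-hot vs `n = 2` smoothing) and evaluated on 40 held-out
crops/class. Reported per seed: mean ordinal error `|true − predicted|`,
severe-error rate (distance ≥ 3), accuracy.

The expected behaviour — and what the acceptance test asserts — is
statistical, not a theorem: across the five paired seeds the smoothed run's
*mean* ordinal error does not exceed the one-hot run's, and within every
seed the severe-error rate never increases. On clean single-cluster crops
the task is easy enough that both losses make only adjacent errors and the
comparison is a coin flip; the effect appears exactly where the smoothing
rationale says it should — ambiguous, occluded, mixed-severity crops.

## Numerical and procedural choices

* **Metrics.** One-vs-rest decomposition of the confusion matrix; macro
  averages are unweighted means over classes. Zero-denominator ratios return
  0 with a flag so empty classes cannot crash a batch run. Display rounding
  is half-up to one decimal in percent; raw values are kept internally.
* **Detection mAP.** Greedy confidence-ranked matching at a fixed IoU
  threshold per class and image; AP is the area under the stepwise
  (all-points) precision–recall curve; mAP averages classes with ≥ 1
  ground-truth box. mAP depends on confidences only through their order.
* **Batch scoring.** Detections match ground truth greedily by confidence at
  IoU ≥ 0.5 (one-to-one). An unmatched ground truth whose best overlap is
  still ≥ 0.1 is tallied under that detection's predicted column; otherwise
  it counts as missed and is reported separately. Unmatched detections count
  against the NILM row, and a normal image with no detections scores one
  NILM/NILM unit — so matrix totals equal the number of scored units.
* **Reference-table note.** The bundled stage-1 matrix reproduces every
  published per-class precision/recall/F cell and the macro F-measure and
  accuracy, but the published stage-1 "average" precision and recall cells
  are not the unweighted means of the per-class values in the same table
  (those means are 61.8% and 64.0%); this package reports the consistent
  macro values. Similarly, the published stage-2 per-class accuracies for
  the atypical classes differ by ≤ 0.6 pp from values recomputed from the
  matrix; only the (consistent) NILM accuracy is used as a regression
  anchor.
* **Defaults.** Smoothing `n = 2`; detector confidence threshold 0.25
  (assumption — inference thresholds are rarely reported); crop margin 10%
  of the box per side. All exposed in the YAML config, which rejects unknown
  keys. Randomness fans out from one master seed through named substreams,
  so adding a consumer never perturbs existing streams.
* **Problem sizes.** Tests and the acceptance script use 128×128 scenes
  (64–96 px crops), 120-scene pipeline datasets, 80/40 crops per class and
  five seeds for the loss study — sizes chosen so the whole stack runs in
  tens of seconds on one CPU while leaving every measured effect outside
  noise.

## Known limitations

The detector stand-in is calibrated to the renderer and is not transferable
to real images; its stage-1 severity grading is intentionally coarse. The
classifier's features assume dark-nucleus/pale-background polarity. mAP on
the synthetic dataset is low in absolute terms because the detector merges
touching clusters and grades coarsely — it is reported as a measured
property of the stand-in, not a performance claim. No confidence intervals
are attached to metrics, and no ROC analysis is provided.
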