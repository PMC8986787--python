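# Methods

## The problem

Assembling labeled training corpora for multi-label medical-image
classifiers is the dominant cost of model development: report-mined (NLP)
labels are cheap but noisy, and expert panels are accurate but cannot scale
to hundreds of thousands of exams. `psimlabel` implements an auto-labeling
framework in which a *validated* classifier labels new image sets itself,
to a user-selected accuracy, and defers everything it is not demonstrably
sure about to a human. The key idea is that "sure" is defined not by the
raw predicted probability but by *similarity to the model's own reference
atlas*, making every emitted label auditable: each positive label comes
with the atlas patches that justify it.

## Scores

For each image and pathology label c the pipeline computes:

**Predicted probability** `y^c` — the unweighted mean over ensemble
members of the sigmoid output of a CAM-capable CNN (convolutional trunk,
global average pooling, one linear layer). Members are trained with the
weighted binary cross-entropy

    L = -alpha(v) * sum_c alpha_s^c [ alpha_P^c t^c ln y^c
                                      + alpha_N^c (1 - t^c) ln(1 - y^c) ]

over tri-valued labels t^c in {1, 0, -1}; -1 (ignore) cells contribute
exactly zero. `alpha_s^c` equalizes classes by their number of non-ignore
cells (max class count / class-c count); `alpha_P^c = (|P|+|N|)/|P|` and
`alpha_N^c = (|P|+|N|)/|N|` rebalance within a class; `alpha(v) = omega >= 1`
up-weights samples from the target view position (members are trained at
several omega values and the ensemble keeps the validation-AUROC-best and
validation-accuracy-best).

**Ensemble CAM** — member CAMs (class weights dotted with final conv
feature maps) are each min-max normalized to [0,1], values below the noise
threshold tau are zeroed (unit step), the surviving maps are summed and the
sum rescaled linearly to peak 1. Member agreement is thereby sharpened and
member-specific noise suppressed. The rescale divides by the peak rather
than min-max normalizing: the sum is already non-negative, and dividing by
the peak preserves the support so that the CAM's nonzero set shrinks
monotonically as tau grows.

**Patch similarity** — the ensemble CAM is upsampled to image resolution,
binarized at half its peak, and the largest one or two connected components
(above an area floor of 0.1% of the image) become bounding-box patches.
Each patch is resampled to 32 x 32 (a 1024-dimensional vector) and mapped
into a shared 2-D embedding fitted with a cosine-similarity neighborhood
objective (UMAP, cosine metric) on the *patch atlas*: patches harvested
from training images the ensemble predicted with probability >= 0.9. The
patch's mean Euclidean distance to its K nearest same-label atlas points
(the *prediction basis*, the evidence surfaced to users) is converted to a
percentile against the atlas's own leave-self-out mean K-NN distance
distribution f_D, and

    patch_similarity = 1 - f_D(mean distance to the K-basis),

the maximum over the image's patches. An input patch inside the atlas
cloud scores near 1; an outlier scores near 0.

**Confidence** — from the *distribution atlas* (the sorted ensemble
probabilities of positive- and negative-labeled training images),

    Confidence_P = max(f_P(y) - (1 - f_N(y)), 0)
    Confidence_N = max((1 - f_N(y)) - f_P(y), 0)

with f_P, f_N the right-continuous empirical CDFs. At most one side is
nonzero; a y between the two distributions (above all negatives, below all
positives) gets (0, 0) — genuinely ambiguous.

**pSim** — for positive candidates (y >= TH_pos), the harmonic mean
`2ab/(a+b)` of Confidence_P and patch similarity (zero if either is zero);
for negative candidates, Confidence_N alone — a negative prediction asserts
the absence of a finding, so there is no patch to match.

## Mode selection and calibration

Per label, records are split at TH_pos into positive/negative candidates;
the candidate's pSim is compared with a calibrated threshold: at or above
it the label is emitted (*self-annotation*, 1 or 0), below it the cell is
deferred (*re-annotation*, -1). Thresholds are the lowest grid values
(grid 0.00..1.00, step 0.01) at which PPV (positive side) and NPV
(negative side) reach exactly 1 with at least one captured record, on a
calibration subset drawn evenly from ten pSim bins (up to 10 per bin,
drawn separately for positive and negative candidates, i.e. up to 100
each) and judged against reader-panel consensus. PPV at zero capture is
reported as missing, never 1, so a threshold can never be selected
vacuously. If PPV = 1 is unattainable the side gets the sentinel threshold
1.0 and nothing is auto-labeled there. Thresholds are frozen after
calibration and applied unchanged to full datasets.

Images with at least one self-annotated *positive* label (and not in the
test set) form the retraining pool; re-annotation cells become ignore (-1)
so the fine-tuning loss skips them. Fine-tuning continues training every
member on original + auto-labeled data at a very small learning rate.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| TH_pos | 0.5 | probability cut separating positive from negative candidates; the natural multi-label operating point |
| tau (CAM noise threshold) | 0.3 | on min-max-normalized member CAMs; removes the diffuse lower third of each map as noise |
| inclusion threshold | 0.9 | only confidently predicted training images contribute atlas patches |
| K (prediction basis) | 5 | enough neighbors for a stable mean distance; small enough to display as evidence |
| D (patch vector) | 1024 (32 x 32) | bilinear resample of the raw image crop, flattened; the minimal faithful derivation of a 1024-d patch descriptor |
| threshold grid | step 0.01 | two-decimal thresholds |
| ensemble | 2 members, omega in {1.1, 1.5} | one member per selection criterion (AUROC / accuracy at 0.5) |
| optimizer | AdamW, lr 3e-3, batch 32, 16 epochs | desk-scale profile; `TrainConfig.full_scale_profile()` restores the full-scale settings (batch 144, lr 1e-4, betas 0.9/0.999, eps 1e-8, weight decay 1e-5) |
| fine-tuning | lr 1e-5, 1 epoch | deliberately gentle: auto-labels should refine, not overwrite, the validated model |

## The synthetic study

No external data is required. The generator emulates the data regime the
framework targets, at desk scale:

* grayscale images (default 64 x 64; the full-scale analog is 512 x 512)
  with a smooth oriented background gradient plus band-limited noise;
* **focal** findings: a soft-edged bright template (peak contrast 0.45) in
  a label-specific quadrant, with a label-specific shape (blob, band,
  diagonal stripe, annulus) — mirroring how real focal findings differ in
  both anatomic location and appearance;
* **global** findings: whole-image haze (brightness +0.10, contrast
  damped to 0.65) — no localized structure at all;
* **mixed** labels draw focal or global per image;
* training labels flipped independently per cell at rate 0.1 (NLP-style
  noise), optional ignore cells;
* a seven-reader panel with per-reader false-positive/false-negative rates
  of 2-6% / 4-10%, consensus by majority (even panels break ties toward
  positive; the reference setting uses an odd panel so ties never occur);
* view position rendered as a darkened top band on non-target views.

The default study uses 2000 training, 400 calibration, 400 test and 400
pool images with three labels (focal, global, mixed), prevalence 0.3.
Under these conditions the ensemble reaches per-label test AUROC of about
0.93-0.99 — the "validated classifier" regime the framework presumes.

What the generator deliberately does **not** model: anatomic structure,
label correlations beyond rendering co-occurrence, reader correlation
(readers err independently), distribution shift between corpora, and
report text. Passing tests therefore demonstrate the *mechanics* of the
framework — that the atlas percentiles, calibration and mode selection
behave as specified and that the accuracy-vs-efficiency trade emerges —
not clinical performance on radiographs.

A consequence worth noting: the mixed label's global variant is rendered
identically to the global label's haze, so images carrying only haze are
intrinsically ambiguous between those two labels. This is intentional —
it reproduces the situation of labels with low inter-observer separability
and keeps the mixed label's AUROC visibly below the focal label's.

## Numerical choices

* Probabilities are clamped to [1e-7, 1 - 1e-7] before logarithms.
* Percentiles are right-continuous ECDFs (ties count as <=), computed by
  binary search on the sorted sample.
* K-NN ties break by atlas insertion order (stable argsort); equal-area
  patch components break toward the top-left bounding box.
* The leave-self-out convention for f_D excludes each atlas point's own
  zero distance, avoiding a degenerate all-zero reference.
* A label with fewer than K+1 qualifying patches is flagged unavailable;
  its positive pSim degrades to Confidence_P alone and the record carries
  the flag. A label with an empty positive or negative probability sample
  has confidence forced to (0, 0).
* An image whose CAM produces no patches scores patch similarity 0, which
  annihilates the positive pSim — a positive label without localizable
  evidence is never self-annotated.
* All randomness flows from one master seed fanned out per stage
  (SeedSequence); reports are byte-identical across runs of the same
  configuration.

## Design decisions that were genuinely open

* **Shared embedding.** One cosine-metric embedding is fitted on all
  labels' patches jointly, with per-label coordinate subsets and per-label
  f_D references. Per-label embeddings would preclude cross-label
  comparisons of basis patches and multiply fitting cost.
* **Multi-patch rule.** With up to two patches per image, the image's
  patch similarity is the maximum over patches — the most
  evidence-favorable reading (one well-matched patch suffices).
* **Negative pSim.** The negative branch uses Confidence_N alone rather
  than a harmonic mean, treating the mode-selection algorithm as normative
  over the general harmonic-mean formula.
* **Patch vectors are raw pixels.** Resampled image crops rather than
  network features: simplest, model-agnostic, and sufficient for the
  atlas retrieval task; deep-feature descriptors are pluggable through the
  embedding contract.
* **Binomial CI dialect** is Wald by default with Wilson behind a flag;
  the bootstrap redraws single-class resamples (bounded retries) so the
  resample count stays fixed.

## Known limitations

* The backbone is a compact three-block CNN; it trains in ~1 minute per
  member on one CPU but is far below radiograph-scale capacity. Any
  classifier exposing `predict_proba` / `feature_maps` / `class_weights`
  can be plugged in.
* UMAP's out-of-sample transform is approximate near cloud boundaries;
  patch-similarity percentiles inherit that.
* PPV/NPV = 1 on a ~100-exam calibration subset does not guarantee
  PPV/NPV = 1 on the population; held-out diagnostics in the report
  quantify the gap.
* Fine-tuning re-uses the frozen atlases and thresholds of the model that
  produced the auto-labels; re-deriving them after fine-tuning would be a
  second calibration round, out of scope here.
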