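# Methods

## Problem and model

Active sacroiliitis in axial spondyloarthritis manifests as bone marrow
edema (BME): hyperintense signal adjacent to the sacroiliac joint on
gadolinium-enhanced fat-suppressed T1-weighted oblique coronal MR slices.
The pipeline decomposes the diagnosis into (i) a per-slice binary
classification of a joint-region patch, (ii) a contextual correction that
exploits the spatial ordering of slices, and (iii) a per-subject decision
rule aligned with the ASAS positivity criterion (≥2 BME lesions on one
slice, or BME on ≥2 consecutive slices).

## ROI geometry

Input annotations are axis-aligned bounding boxes of the left and right
iliac bones (0-based, half-open, row-major). For the left box with columns
`[a, b)`, width `W = b − a` and center `m = ⌊(a+b)/2⌋`, the left ROI keeps
the box rows and spans columns `[m, m + ⌊f·W⌋)` with shift fraction
`f = 0.8` by default: it starts at the iliac center and reaches medially
across the joint space into the sacral half, where lesions sit. The right
ROI is constructed as the mirror image (its center uses the ceiling of the
midpoint so that symmetric annotations give exactly mirror-symmetric
ROIs). Both crops are clipped to the image; if their heights differ, the
shorter crop is symmetrically extended *from the source image* to the
taller height, so concatenation never interpolates. The combined patch is
bilinearly resized to the classifier input (224×224 for the ResNet-style
backbones; the bundled experiments use 64×64 with the tiny backbone).

The verbal description this rule formalizes is ambiguous about what
"inward by 0.8 times the width" is anchored to; anchoring at the box
center and extending medially is the reading that covers the joint space
plus the sacral half and keeps left/right symmetry. The fraction is a
config knob.

## Noise model

Every image — later used for training, validation or testing alike —
receives additive acquisition-style noise: a zero-mean Gaussian per pixel,
plus a Poisson-derived component whose expectation follows
`λ = (ln(255·p + 1))⁴` on the 8-bit scale, where `p` is a single pixel
value drawn uniformly at random from the image ("single_pixel" rule; a
"per_pixel" variant evaluates the rule at each pixel). The deviates are
rescaled by 1/255 and the result is clipped to [0, 1].

The configured default Gaussian variance is 0.3. On [0, 1] intensities
this corresponds to σ ≈ 0.55 — larger than the full dynamic range — and
essentially whitens the image; likewise the single-pixel Poisson rule adds
a mean shift of order 1 for typical pixel values. The defaults are kept
for fidelity to the design being reproduced, but the bundled experiment
configuration uses a Gaussian variance of 0.005 and disables the Poisson
component, which keeps the noise stage active at a level compatible with
the [0, 1] intensity scale. The intensity scale on which the original
values were meant to apply is unknown.

## Classifier and training

The slice classifier is a CNN over single-channel patches with a fully
connected head of one hidden layer (default width 32) and sigmoid output
nodes. Two output modes exist: `two_node` (one sigmoid node per class,
trained with per-node focal loss on one-hot targets) and `single_logit`
(one sigmoid node for the positive class). The decision threshold is 0.5
on the positive-class score.

Focal loss is `FL(p) = −α (1−p)^γ ln p` with the true-class probability
`p`, defaults α = 0.25, γ = 2 (the standard values of the loss's original
formulation; no task-specific values are prescribed), ε-clamped at 1e−7.
With γ = 0, α = 1 it reduces exactly to binary cross-entropy.

Training uses SGD with momentum 0.9, batch size 32, batch normalization,
and a cosine-decayed learning rate from η₀ = 0.03 to 0 over the configured
epochs (default 50). Augmentation applies horizontal flips (p = 0.5) and
rotations drawn uniformly from ±15° with replicate-border fill; random
cropping is deliberately not offered because a peripheral lesion could be
cut off. Inputs are standardized with the training set's global mean and
standard deviation (stored with the model); no pretrained initialization
is available in this package — there is no bundled weight source — so
`pretrained=True` raises, and transfer learning is out of scope.

The layer stack (`sijbme.nn`) is a small numpy implementation with
explicit forward/backward passes, verified against central-difference
gradients. Backbones: `tiny` (three conv/BN/ReLU/pool blocks, flattened
into the dense head) for CPU-scale experiments, and five-stage `resnet18`
/ `resnet50` style builders (7×7/64 first stage; 3×3 basic residual
blocks; 1×1–3×3–1×1 bottlenecks from the third stage for resnet50) for
architectural fidelity. Training is deterministic for a fixed seed under
single-threaded execution.

## Sequence correction and subject decision

Per subject, slice decisions ordered lower → upper pelvis form a binary
vector. A size-3 sliding median with replicate padding removes isolated
positives and restores isolated negatives inside runs. Replicate padding
(the boundary value is repeated) was chosen because it never erodes a
genuine boundary run of two positives; the filter is idempotent on binary
sequences (checked exhaustively up to length 10 against a brute-force
oracle).

The default subject rule is *any-positive on the filtered vector*: under a
size-3 median this fires exactly when the raw vector contains two adjacent
positives (with a boundary slice counting as its own neighbour under
replicate padding), which mirrors the consecutive-slice clause of the ASAS
rule and maximizes sensitivity. A `mean_threshold` rule (positive iff the filtered
mean exceeds τ) is provided as the averaging alternative; the exact
averaging threshold used in the original design is unstated, and τ = 0
reproduces any-positive.

## Metrics and protocol

Accuracy, recall, precision, specificity, NPV and F1 are reported as
percentages from the 2×2 confusion table; NPV is `TN/(TN+FN)` (the
standard definition; note that with zero false negatives recall and NPV
are both exactly 100%). Zero-denominator metrics are reported as NaN, not
0, so fold averages are never inflated. AUC is the rank statistic with
ties counted ½ (computed via scikit-learn, cross-checked against a
pairwise brute-force oracle in the tests). The protocol draws five
independent stratified subject-level 70/30 splits (slices never cross the
boundary) and aggregates per-fold metrics as mean ± sample SD. Averaging
F1 across folds differs from the F1 of averaged precision/recall; the
report keeps per-fold values so either can be formed.

## Grad-CAM

Saliency for a target class is the ReLU of the feature maps of the last
convolutional stage weighted by the spatial average of the class logit's
gradient, bilinearly upsampled to the patch and max-normalized (both
choices are free parameters of the method; max normalization makes the
peak location invariant under monotone rescaling of the logit). The
localization check is statistical — the peak must fall in a slightly
dilated lesion mask in ≥70% of trained true positives — because saliency
can legitimately latch onto confounders (e.g. bright sacral bone) in a
minority of cases.

## Synthetic phantom

The phantom generator replaces unavailable clinical data. Each subject is
a stack of 96×96 slices (4–23 for positive subjects, 18–25 for controls,
matching the emulated cohort's ranges) containing two lateral bright
ellipses (ilium, intensity 0.55), a central ellipse (sacrum, 0.92× bone),
and dark joint lines; ellipse sizes taper smoothly toward the ends of the
stack. Iliac bounding boxes are derived from the rendered ellipses.
Positive subjects receive a run of ≥2 consecutive lesioned slices (lesion
centers drifting ≤2 px between neighbours), sometimes plus a second lesion
on one slice, placed at the medial iliac edge on the joint line; every
generated positive subject provably satisfies the ASAS rule, and slices
are labeled positive exactly when they carry a lesion. Lesions are discs
of radius 2–4 px at intensity `bone × (1 + contrast)` (default contrast
0.5; the separability experiments use 0.8). Mild Rician-like magnitude
noise (σ = 0.015) is added at render time. Lesion size/contrast
distributions of real cohorts are unknown; these are knobs, not estimates.

What the phantom does **not** emulate: true MR physics (k-space, bias
fields, partial volume), anatomical shape variability, structural lesions
(erosion, sclerosis, ankylosis), fat-suppression artifacts, or ambiguous
lesion boundaries. Passing the bundled experiments therefore demonstrates
that the pipeline's machinery is correct and that the stages compose as
designed — not that the classifier would reach comparable accuracy on
clinical data, where reported performance of this design is in the low-90s
percent range at slice level rather than ~100%.

## Experiment sizes and numerical choices

The bundled end-to-end experiments use a 20-subject cohort (14 positive /
6 negative, the emulated cohort's class ratio), 64×64 patches, the tiny
backbone, 30 training epochs and two split repeats — sizes chosen so the
full suite runs comfortably on a single CPU while leaving the training
dynamics (imbalance, focal loss, schedule) intact. Determinism: all
randomness flows through seeded numpy generators; probabilities are
clamped to [1e−7, 1−1e−12] inside the focal loss and its gradient; batch
norm uses momentum 0.1 and ε = 1e−5; degenerate inputs (empty sequences,
zero-width boxes, single-class truth vectors) raise errors rather than
returning silent defaults.

## Known limitations

- Slice classification of subjects whose positivity rests on a single
  minimal run (exactly two small-radius lesioned slices) is the fragile
  case: one missed slice makes the subject invisible to the median-filter
  + any-positive rule. This mirrors the clinical edge case and is visible
  as occasional sub-100% subject recall on harder random cohorts.
- The ResNet-style backbones are architecturally faithful but impractical
  to train at scale in pure numpy; they are exercised structurally in the
  tests, while the tiny backbone carries the end-to-end experiments.
- No pretrained initialization; transfer learning cannot be reproduced
  offline.
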