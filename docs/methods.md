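# Methods

This note documents the models, procedures and design decisions behind
`woundseg`: what the pipeline computes, what the synthetic data does and
does not emulate, and which numeric choices are package decisions rather
than mathematical necessities.

## Problem setting

Training a segmentation network normally requires a large set of
manually annotated masks. The pipeline implemented here removes the
manual-annotation bottleneck for binary wound segmentation by combining
two ideas:

* **Transfer learning (TL).** A model trained on a *source domain*
  (a different wound-image distribution) produces initial masks for the
  unlabeled *target* dataset. No target annotation exists at this point.
* **Active semi-supervised learning (ASSL).** Each predicted mask is
  shown to a reviewer who only *accepts or discards* it — a decision of
  seconds, versus minutes for drawing a mask. Accepted masks become
  pseudo-labels. Each round, the model is reset to the pretrained
  weights, retrained on the current pool, and re-run over the whole
  dataset; newly accepted predictions grow the pool.

The loop stops when the fraction of accepted segmentations over the
whole dataset reaches a target (default 80%), when a round cap is hit,
or when the accepted count stops improving (plateau).

Two details of the round structure matter and are enforced as tested
invariants:

* **Weight reset.** Every round starts from a bit-identical copy of the
  pretrained weights, not from the previous round's weights. This keeps
  each round a fresh transfer-learning run on a larger pool and avoids
  compounding drift from training on pseudo-labels.
* **Frozen validation split.** The labeled pool is split 90/10
  (train/validation) when the first training round starts. The
  validation ids are drawn once and held fixed; samples accepted later
  join the training side only. F1/IoU are reported against the pool's
  pseudo-labels, so they measure self-consistency of the pipeline, not
  agreement with ground truth (on real data no ground truth exists).
  Accepted pseudo-labels are permanent: they are never re-validated or
  replaced in later rounds, which is what makes pool growth monotone.

## The acceptance oracle

Reviewers judge three binary criteria: (i) the mask covers the entire
wound; (ii) it covers only the wound — no holes or spurious parts;
(iii) its shape follows the wound boundary. These are qualitative; to
run the loop unattended on synthetic data the package operationalizes
them against ground truth:

| criterion | computable predicate | default threshold |
|---|---|---|
| (i) covers | recall ≥ `min_coverage_recall` | 0.90 |
| (ii) only wound | precision ≥ `min_precision`, enclosed-hole area ≤ 1% of the mask, no foreground component beyond the largest | 0.90 / 0.01 / 0 |
| (iii) boundary | symmetric mean contour distance ≤ 2% of the image diagonal | 0.02 |

All thresholds are package decisions (`ValidationThresholds`), exposed
in configuration. They were chosen so that a perfect mask always passes
and each corruption mode of the synthetic generator at severity ≥ 0.3
fails exactly its targeted criterion; both properties are tested.
Criterion (ii) combines a precision floor with explicit topology checks
because "no holes or spurious parts" names both an over-segmentation
failure and a topological one — precision alone would miss a small far
away blob on a large wound.

The oracle consumes only masks, never image pixels, so it is a pure,
reproducible function. Holes are detected as connected components of
the mask complement that do not touch the raster border; the boundary
distance is the symmetric mean of nearest-contour-pixel distances
computed with Euclidean distance transforms.

The package does not model disagreement between multiple reviewers; the
oracle is a single deterministic decision-maker. An interactive review
mode (CLI `review`) records human accept/discard decisions for real
data, where no ground truth exists.

## Metrics and loss

Pixel-level precision, recall, F1 = 2PR/(P+R) and IoU = TP/(TP+FP+FN),
with foreground as the positive class. F1 and IoU derived from the same
counts obey F1 = 2·IoU/(1+IoU) exactly; the test suite checks this to
1e-12 on randomized counts, and it is why a reported IoU of 0.96 must
pair with an F1 of 0.98. Degenerate convention: any 0/0 ratio is 0,
except when prediction and reference are both empty, which counts as
vacuous success (all metrics 1). The convention only matters for edge
cases; reference masks are non-empty by construction.

Training minimizes the standard binary focal loss

    L = mean[ −α·y·(1−p)^γ·log p − (1−α)·(1−y)·p^γ·log(1−p) ]

with α = 0.25, γ = 2 by default, probabilities clipped to
[1e-7, 1−1e-7]. γ = 0, α = 0.5 reduces it to exactly half the binary
cross-entropy (tested to 1e-6); since Adam's update is invariant to a
constant gradient scale, such a run reproduces cross-entropy training
dynamics. A β parameter is carried in `FocalLossParams` for
configuration compatibility but does not enter the loss; it is
documented as inert. The reduction is the mean over pixels, making the
loss value resolution-independent.

Round metrics default to per-image means; pixel-pooled aggregation is
available through the metrics module by pooling confusion counts first.

## Segmentation model

`UNetSegmenter` is an encoder–decoder with skip connections and a
single-logit sigmoid head, implemented in NumPy (`woundseg._nn`):
same-padded 3×3 convolutions, ReLU, 2×2 max-pooling, nearest-neighbour
upsampling, hand-derived backpropagation, Adam. Writing the engine in
NumPy keeps the whole pipeline bit-deterministic given a seed — forward
passes, gradients, shuffling and augmentation draw from seeded
generators and nothing else — which the reproducibility guarantees
(identical histories from identical seeds) rely on.

Backbone presets are capacity variants of the same architecture:
`tiny` (2 downsampling stages, base width 8, ~30k parameters; trains at
64×64 on one CPU in minutes), `small` (width 16, ~118k) and `large`
(3 stages, width 16, ~487k). The tiny preset is the default and the one
used by every benchmark in this package; the larger presets exist for
capacity-ordering experiments and slower full runs.

Protocol defaults follow the full-scale recipe: 100 epochs of Adam at
learning rate 1e-5, batch size 8 (a package choice; no canonical value
exists), augmentation restricted to horizontal and vertical flips, each
applied with probability 0.5 to image and mask jointly. Desk-scale runs
(`woundseg.benchmark`) override this to 30–40 epochs at 1e-3: a
from-scratch tiny network at 64×64 needs the larger step size to
converge within minutes, and the package treats that scaled-down
protocol as its own study condition.

Preprocessing: inputs are resized to the working resolution (bilinear
for images, nearest for masks, so labels stay hard), scaled to [0, 1],
then standardized per image and channel (subtract mean, divide by
standard deviation). The standardization removes global gain and most
gamma variability, which is the right invariance for a dataset whose
images vary mainly in illumination and exposure. Predictions are
binarized at probability 0.5 (inclusive) and returned at the original
image resolution via nearest-neighbour upsampling.

Model states serialize to an `.npz` weights file plus a JSON sidecar
(architecture, provenance); save→load→predict is bit-exact.

## Synthetic data

No public pet-wound segmentation dataset exists, so the package ships a
generator that emulates the *statistical structure* of such data — not
its photorealism — to make every pipeline stage testable:

* **Wound shape**: union of 1–3 overlapping random ellipses, smoothed;
  satellites are centred inside the main ellipse, guaranteeing a single
  connected component. Area fraction is controlled by iterative
  rescaling into a configured range (default 6–25% of the image; no
  quantitative size distribution exists for real pet wounds, so the
  range is a package choice covering small-to-large wounds).
* **Appearance**: wounds are a reddish hue family composited with a
  soft (Gaussian) edge; backgrounds draw from skin-like, fabric-like and
  flat-colour families; global per-image gain (0.75–1.25) and gamma
  (0.8–1.25) emulate illumination and exposure variability; pixel noise
  and four camera tags emulate device heterogeneity.
* **Difficulty knob**: a configurable fraction of samples (default 0.5)
  is rendered "hard" by planting 1–3 wound-like *distractor* spots in
  the background (soft-edged ellipses of the wound's own texture,
  radius 3.5–7 px, kept clear of the true wound), with a graded
  strength factor from `distractor_strength_range` (default 0.3–1.0)
  that blends them from invisible to fully wound-coloured. A model that
  fires on a distractor produces a spurious foreground component, which
  the oracle rejects outright; a model that has learned the dataset's
  size-and-position regularities suppresses them. This axis has the two
  properties the loop's growth dynamics need. First, failure is
  *binary and label-preserving*: the true wound's mask stays crisp
  whether or not the distractor fools the model, so accepted hard
  samples contribute clean pseudo-labels. Second, suppression
  *generalizes up the strength axis* once examples of weaker
  distractors are in the pool. Two earlier designs were abandoned
  after measurement: blending the wound toward the background destroyed
  the boundary signal-to-noise, so accepted hard masks were borderline
  and the pool's label quality collapsed (the loop stalled); shifting
  the wound hue kept labels crisp but a normalized blob detector
  generalizes across hue essentially for free, so nothing was hard and
  round 0 was already near-total.
* **Two style families**: `target` (the working dataset) and `base`
  (the pre-training source domain: a restricted background palette, a
  slightly different wound-hue regime, an unrelated seed, and — the
  decisive difference — *no distractors*). A base-trained model
  segments distractor-free target images nearly perfectly but fires on
  distractor spots, which makes round-0 transfer partial: the source
  model annotates roughly half to two-thirds of the default dataset
  (seed-dependent) and the loop must earn the rest. The base-trained model is a stand-in for an
  externally pretrained human-wound model, which is not publicly
  available; the package reproduces the *structure* of the transfer
  (source domain → target domain), not the original weights.

Everything is a pure function of the configuration including its seed
(per-sample streams derive from `(seed, index, style)`), so identical
configs give byte-identical datasets.

`corrupt_mask` produces systematically wrong masks for testing the
oracle: boundary peeling (under-coverage), interior carving (holes),
disjoint blobs (spurious components) and smooth boundary displacement
with exact area preservation (jitter). Severity scales each effect
monotonically; severity 0 is the identity. The jitter amplitude
(12·severity px of a smoothed unit-variance field added to the signed
distance function) was calibrated so severity 0.3 exceeds the default
boundary tolerance at 64×64.

What passing synthetic tests does **not** show: robustness to real
photographic nuisances (specular highlights, fur occlusion, bloodstains,
perspective, motion blur), multi-species appearance, or reviewer
subjectivity. Results on the generator demonstrate that the *machinery*
— loop accounting, oracle gating, transfer structure, determinism — is
correct, and that the growth dynamics appear when a graded difficulty
axis exists; they are not evidence about clinical images.

## The desk-scale benchmark

`woundseg.benchmark` fixes one canonical experiment: 200 target images
(generator seed 42, defaults above), a tiny U-Net pretrained for 40
epochs on 120 base-style images, then up to five ASSL rounds of 30
epochs each at learning rate 1e-3, simulated oracle at default
thresholds, 90/10 split, target 80%. A complete run takes roughly ten
minutes on one CPU. The generator seed is part of the benchmark
definition; the run seed steers training and split randomness.

Problem sizes elsewhere follow the same logic: structural tests use a
50-image, 3-round, 10-epoch mini run, and the determinism check uses a
20-image, 2-round, 4-epoch run — large enough to exercise every code
path, small enough to keep the full suite in minutes.

## Numerical and procedural choices

* Binarization threshold 0.5, inclusive (`p ≥ t`): a uniform 0.5 map
  becomes all-foreground, which the degenerate-model tests rely on.
* Split rule: `n_val = max(1, round(val_fraction · n))`. For a pool of
  143 at 10% this gives 129/14; an explicit `val_count` override exists
  because other rounding conventions (e.g. a fixed 16-image validation
  set) appear in practice.
* Round seeds derive as `base seed + round index`: rounds are
  reproducible but not identical.
* Rejected images are re-predicted with fresh masks each round (the
  model changed); accepted ones are never re-predicted.
* Max-pool gradients split ties evenly; with float32 activations ties
  are rare and the choice is immaterial but deterministic.
* `bootstrap_round0` reports a warning state (not an exception) when
  the pretrained model yields zero accepted masks, since that is a
  legitimate outcome of a failed transfer.

## Known limitations

* The NumPy engine is single-threaded and desk-scale by design; the
  `large` preset at high resolution is out of its intended envelope.
* The oracle's thresholds encode one reasonable reading of qualitative
  clinical criteria; real reviewer decisions will not match any fixed
  threshold set exactly.
* Pseudo-label error compounds across rounds by construction (accepted
  masks are permanent); the weight reset and the acceptance gate bound
  but do not eliminate it. On synthetic runs this appears as occasional
  round-to-round dips in the whole-dataset accepted count while the
  pool itself keeps growing.
* F1/IoU round metrics are computed against pseudo-labels, and are
  therefore optimistically biased relative to ground truth — the same
  caveat applies to any pipeline that validates on its own accepted
  predictions.
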