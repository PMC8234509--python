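# Methods

## Problem and scope

Capsule endoscopy (CE) produces tens of thousands of small-bowel frames
per examination, and the fraction of mucosa left visible — not obscured
by air bubbles, bile or debris — determines how trustworthy a reading
is. `cescore` implements an automated cleansing-quality pipeline: each
frame receives a 5-point cleansing score from the proportion of visible
mucosa, the case-level *final cleansing score* is the mean of the
per-frame scores, and the case is graded A/B/C on a validated
quantitative scale whose adequacy call (A or B = adequate) is what a
clinical report needs. No public frame-level dataset with cleansing
labels exists, so the package ships a synthetic-frame generator with
exact ground truth; every downstream stage is validated against that
ground truth.

## Score semantics

The per-frame score bins the visible-mucosa fraction *v*:
score 1 for *v* < 0.25, 2 for [0.25, 0.50), 3 for [0.50, 0.75),
4 for [0.75, 0.90], and 5 strictly above 0.90. The bin edges at 0.25,
0.50 and 0.75 are lower-inclusive; 0.90 itself still scores 4 because
score 5 demands *more than* 90 % visible mucosa. `fraction_to_score`
is monotone by construction.

## Preprocessing channels

Scorers never see raw RGB. Each frame is reduced to three planes chosen
so that each occluder kind is separable from mucosa in at least one of
them: Rec. 601 gray (bubbles bright, debris dark), HSV saturation
(bubbles nearly achromatic against strongly coloured mucosa) and CIELAB
b* (bile strongly yellow). Gray and saturation are computed directly
from their closed forms; Lab conversion uses scikit-image's sRGB/D65
implementation and the b* plane is rescaled affinely from [-128, 127]
to [0, 1], which preserves order and keeps the achromatic point at
128/255 ≈ 0.502. The native Lab-b range is signed and no published
rescaling convention exists for it, so the affine map is our choice;
the white point is assumed D65 because the frames are ordinary sRGB
images. A circular-mask helper exists for real capsule frames with dark
round borders; synthetic frames have none, so it is off by default.

## Synthetic data generator

A frame is a reddish-pink mucosa field (base RGB (195, 85, 95), low-
frequency smooth noise of amplitude ~±20 per channel from an 8×8 grid
upsampled with cubic interpolation) over which occluders are placed
greedily, largest first, until the occluded-pixel budget implied by the
requested visible fraction is met. Overlap is allowed; the budget is
measured on the union mask; and the ground truth of record is the
fraction computed from that final union mask, not the request. Each
placement is centred on a still-uncovered pixel, so the loop always
progresses; a placement that would overshoot the budget by more than
0.5 % of the frame is shrunk before being accepted. Achieved fractions
land within 0.02 of the request at the default 64×64 size (tests check
this), and full occlusion (visible fraction 0) is exact.

Occluder appearance is tuned to the physics of each artefact, not to
photorealism: bubbles are bright low-saturation discs with a lighter
rim, bile is an alpha-blended (0.72–0.85) yellow-green irregular patch,
debris a dark brown noisy blob. The palette deliberately gives each
occluder a clear signature in exactly the channel that motivates the
channel choice — only the *relative* channel statistics matter to the
scorers. Cases follow a cleanliness trajectory along the frame index
(constant, linear, piecewise-linear, or a reflected Gaussian random
walk with step SD 0.05–0.08 by default, emulating slow drift of
preparation quality along the bowel); per-frame seeds derive from the
case seed, so cases are bit-reproducible.

What the generator does *not* emulate: real mucosal texture and villi,
specular highlights, lesions and bleeding (excluded from the clinical
curation this mirrors), illumination fall-off, or the resolution of a
real capsule camera. Consequently, passing the synthetic-recovery tests
shows the *procedures* are correct — that the channels separate the
occluders they were chosen for, and that scoring, aggregation, grading
and evaluation compose correctly — not that the trained weights would
transfer to clinical frames.

## Rule-based scorer

A pixel is bubble if gray > 0.75 and saturation < 0.25; bile if
Lab-b > 0.65; debris if gray < 0.20; the visible fraction is the
complement of the union. The thresholds sit midway between the mucosa
statistics and the occluder statistics and are exposed in
`RuleThresholds` for tuning on other material. On synthetic frames this
estimator is nearly exact by design (the generator and the rules agree
about what an occluder looks like); its role is to provide a fully
transparent baseline and an independent scoring path through the
pipeline.

## Convolutional scorer

The learned scorer is a deliberately small CNN: three 3×3 same-padded
conv blocks (16/32/64 channels, ReLU, 2×2 max pool), global average
pooling, a dense layer to 5 logits, and a softmax. The [0, 1] channel
planes are centred (x − 0.5) on entry: without centring the all-positive
inputs condition the first layer poorly and the short training schedule
underfits. It is implemented
directly in numpy (im2col convolutions evaluated as BLAS matrix
products; the backward pass is exact, finite-difference-checked in the
tests), trains on a CPU in minutes at 64×64, and is bit-deterministic
under a fixed seed.

Training minimises categorical cross-entropy with RMSProp (ρ = 0.9,
ε = 1e-8) in two phases: the full network at learning rate 0.001, then
a fine-tuning pass over all layers at 0.00001. A `head_only_initial`
flag restricts the first phase to the dense head for transfer-style
schedules; it is off by default because with random initialisation a
frozen feature extractor learns nothing. Defaults: 10 + 5 epochs,
batch 32 — small enough for desk-scale data, large enough to converge
on it.

Reference scores are themselves subjective near bin boundaries, so
uncertainty between two adjacent scores is tolerated: with smoothing
s (default 0.1) the training target gives each adjacent score mass s
and the true score the remainder — (…, s, 1−2s, s, …) in the interior
and (1−s, s) at scores 1 and 5, so targets always sum to one. At
inference the score with the highest softmax probability is assigned;
exact ties break toward the lower score, the conservative direction
(flags worse cleansing).

## Aggregation and grading

The final cleansing score is the plain arithmetic mean of the ordered
per-frame scores (reported full-precision, displayed to one decimal).
For grading, the case is split into contiguous thirds in time order —
proximal, middle, distal; when the frame count is not divisible by 3
the earlier segments take the extra frames (fixed, documented
convention). Each segment's grade 1–4 comes from the fraction of its
frames showing > 50 % invisible mucosa: < 5 % → 1, 5–15 % → 2,
15–25 % → 3, > 25 % → 4, with lower-inclusive bins and grade 4 strictly
above 25 % as the scale prints it. With integer scores, "> 50 %
invisible" is exactly "score ≤ 2" because the 50 % visibility boundary
separates scores 2 and 3; when raw estimated fractions are available a
direct `visible < 0.5` test can be selected instead (`grading_mode:
fraction`). The three segmental grades sum to 3–12 and map to A (3–5),
B (6–8), C (9–12); adequacy is A or B. Enumerating all 4³ = 64 triples
gives 10 A, 34 B, 20 C — a frozen truth-table test.

## Evaluation statistics

Agreement between two per-frame score sequences is summarised from the
5×5 confusion matrix (rows: reference, columns: predicted): Top-1
accuracy is the trace over the total; Cohen's kappa is
(Po − Pe)/(1 − Pe) with Pe the sum over scores of the products of the
marginal proportions; the misclassified mass splits into
under-estimation (predicted < reference, the lower triangle) and
over-estimation. Kappa is undefined when Pe = 1 (all mass in a single
cell) and raises rather than returning a number.

The case-level ROC treats "adequate" as positive and predicts adequate
when the final score is ≥ the threshold; every distinct observed score
is a candidate threshold. AUC is computed by the trapezoidal rule over
the empirical curve, which equals the Mann–Whitney concordant-pair
statistic with half-credit for ties (a property test checks the
equality on random instances). The operating cut-off maximises
Youden's J = sensitivity + specificity − 1, ties broken toward the
lower threshold, and is *reported* as the midpoint between the chosen
threshold and the next lower distinct score — the form in which such
cut-offs are conventionally quoted (e.g. 2.95 when the straddling
scores are 2.8 and 3.1). Whether the clinical rule was ≥ or > is not
recoverable from a reported midpoint; we fix ≥ and document it. Group
comparison across grades reports per-group mean, SD and t-based 95 %
CI, plus a one-way F test; post-hoc tests are out of scope.

## Numerical and design notes

* All randomness flows from explicit seeds; per-case and per-frame
  seeds derive from the run seed via `SeedSequence`, so partial re-runs
  are reproducible and the end-to-end pipeline is byte-identical across
  runs with one seed.
* The network trains in float32 (softmax/loss in float64); training is
  deterministic on fixed hardware but bit-level results can differ
  across BLAS builds — the tests assert determinism within one machine.
* Degenerate inputs fail loudly: empty score sequences, cases with
  fewer than 3 frames, single-class training sets, single-class ROC
  labels, out-of-range fractions/scores, malformed CSV rows (reported
  with row numbers).
* Problem sizes used by the shipped experiments: 64×64 frames; 500
  frames (100 per score) for rule-based recovery; 2,500 training and
  500 held-out frames for the CNN; 100 random instances for each oracle
  check; 3 cases × 12 frames for the determinism run. These sizes make
  the full suite comfortably reproducible on a single CPU.

## Known limitations

* Synthetic frames are far easier than clinical ones; the published
  clinical figures (93 % Top-1, kappa 0.672, AUC 0.913, cut-off 2.95)
  require the original 400,000-frame clinical dataset and are not
  reproducible here — only the procedures that produced them are.
* The rule-based estimator's thresholds are tuned to the synthetic
  palette; on real frames they would need recalibration.
* The CNN is a minimal architecture for 64×64 inputs, not a clinical
  model; no pretrained weights are shipped.
* Segment boundaries assume the manifest covers exactly the small-bowel
  section; landmark detection (pylorus/cecum) is out of scope.
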