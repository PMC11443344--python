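# Methods

This note documents the models and procedures implemented in `chillgrade`, the
choices made where the design was genuinely open, and what the synthetic data
can and cannot show about real instrument imagery.

## Problem setting

Chilling injury (low but non-freezing temperature stress, roughly 0–12 °C)
depresses photosystem-II activity before visible symptoms appear.
Pulse-amplitude-modulated (PAM) chlorophyll-fluorescence imagers resolve this
spatially: the fluorescence-yield raster is rendered as a pseudo-color image in
which healthy leaf tissue appears red, injured tissue yellow-green and the
non-leaf background black.  The package grades each leaf by the injured-area
ratio, describes it with 36 image features, screens those against the grade by
rank correlation, and classifies the screened features with a bidirectional
LSTM tuned by the dung-beetle optimizer (DBO).

## Injury grading

The severity measure is the injured-pixel fraction

    Lk = N1 / N

(injured pixels over leaf pixels), mapped to four grades: A (sound,
Lk < 5 %), B (slight, < 15 %), C (moderate, < 30 %), D (severe, ≥ 30 %).
The published band edges leave Lk = 5 %, 15 %, 30 % unassigned ("<" on one
side, ">" on the other); the implementation closes each band on the left, so
0.30 is grade D.  This makes the mapping total and deterministic; any other
edge convention changes only measure-zero inputs.

Segmentation is deliberately plain HSV thresholding (`SegmentationConfig`):
brightness (V > 0.12) separates leaf from the near-black background, a hue
window ([0.12, 0.40], i.e. yellow through green) separates injured from
healthy (red) tissue, and connected components below 0.1 % of the image area
are dropped as speckle.  Thresholds are configuration, not constants, because
real PAM pseudo-color lookup tables vary by instrument; the defaults are tuned
to the synthetic convention below and leave a guard gap of ≈ 0.05 in hue on
both sides.

## The 36 features

Over the leaf mask, per image:

* **18 color features** — means of R, G, B (0–255), H, S, V (in [0,1]) and
  CIELAB D65 L*, a*, b* (L in [0,100], a/b signed), plus the nine ratios
  G/R, G/B, B/R, S/H, V/S, V/H, L/a, L/b, b/a of those means.  Ratio
  denominators are guarded by `sign(y)·max(|y|, 1e-9)`: a plain
  `max(y, 1e-9)` guard would silently flip the sign of L/a and b/a on green
  tissue, where a* is negative, and those signs carry information.
* **4 histogram features** — mean, standard deviation, cube-root third
  central moment and smoothness `R = 1 − 1/(1 + (σ/255)²)` of the gray-level
  histogram.  Two printed conventions were normalized to standard practice:
  the moment formulas are histogram-weighted (the unweighted forms are
  degenerate — they would not depend on the data), and σ is scaled by 255 in
  the smoothness so that R spans [0, 1) instead of saturating at ≈ 1 for
  every natural image.
* **6 gray-gradient co-occurrence (GGCM) features** — low/high gradient
  advantage, gray and gradient distribution non-uniformity, gradient mean and
  standard deviation, from the joint histogram of quantized gray level
  (Ng = 16 uniform bins over [0,255]) and quantized 3×3-Sobel gradient
  magnitude (Ns = 16 uniform bins over the observed maximum; a constant image
  puts all mass in the lowest bin).  The low/high threshold defaults to
  T = Ns/2 = 8, the midpoint of the gradient axis; T is otherwise
  unconstrained, so it is exposed in `FeatureConfig`.  The gradient-standard-
  deviation formula is read as `sqrt(Σ (j−μ)² P_j)`; the ambiguous printed
  subscript admits no other reading that yields a standard deviation.
* **8 gray-level co-occurrence (GLCM) features** — energy (ASM), entropy,
  inertia and correlation of the symmetric co-occurrence matrix at distance 1
  for the four offsets (0°, 45°, 90°, 135°), each summarized by its mean and
  population standard deviation over the four directions (that is what makes
  the "standard deviation of energy/…" features exist).  Entropy carries the
  standard leading minus sign (≥ 0); correlation is defined as 0 when a
  marginal standard deviation vanishes.  16 quantization levels by default.
  Pairs are counted only when **both** pixels are inside the leaf mask
  (background is not tissue); the implementation maps off-mask pixels to a
  sentinel level and discards its row/column after counting.

Every histogram/GGCM/GLCM feature is checked in the test suite against an
independent brute-force summation (explicit loops, hand-convolved Sobel,
pair enumeration) on random ≤16×16 images at 1e-9, and the color descriptors
against per-pixel `colorsys` and textbook sRGB→Lab conversions at 1e-6.

## Feature screening

Each feature is scored by Spearman rank correlation with the numeric grade
level 1–4.  Grade labels are massively tied, so the tie-corrected estimator
(product-moment correlation of average ranks; `scipy.stats.spearmanr`) is
used; with no ties it reduces to the classical `1 − 6Σd²/(n³−n)` form.  A
constant feature gets ρ = 0 with a warning rather than NaN.  |ρ| is binned as
weak [0, 0.3), moderate [0.3, 0.5), strong [0.5, 0.8), very strong [0.8, 1];
two published bin conventions conflict, and the one actually used to assign
groups (e.g. |ρ| = 0.555 called "strong") is implemented.  The very-strong
group becomes the classifier input, in feature order.  On the study's own
imagery that group is the nine gray-image features (histogram mean/sd/skew/
smoothness, low/high gradient advantage, gray/gradient non-uniformity,
gradient mean); on synthetic data the selection is recomputed and is
typically larger, because every color channel also tracks the injured
fraction there.  Screening is computed on the training split only by
default — screening on all data before splitting would leak.

## BiLSTM classifier

Each sample is fed as a sequence of scalar time steps (one selected feature
per step, in feature order) to a forward and a backward LSTM cell with the
standard input/forget/output gates and cell state.  The final hidden state of
each direction is concatenated and passed through a dense softmax head over
the four grades; the published combination `h = α·h_f + β·h_b` gives no
values for α, β, and a dense head over the concatenation subsumes any fixed
choice.  The stack is plain numpy with hand-written
backpropagation-through-time, validated against central finite differences
(max component error < 1e-6 in the suite).

Training: full-batch Adam (β₁ = 0.9, β₂ = 0.999), cross-entropy plus
`0.5·λ·Σw²` on the weight matrices, global gradient-norm clipping at 1,
features z-scored with training-split statistics, forget-gate bias
initialized to 1, Glorot-uniform weights, and a single learning-rate drop by
factor 0.1 at epoch ⌈max_epochs/2⌉ (only the factor is published, not the
schedule; one mid-training drop is the simplest schedule that uses it).
Baseline hyperparameters: 200 hidden units, learning rate 0.001, L2 0.001,
500 epochs.  Everything is seeded; build/train/predict are bit-reproducible.

## Dung-beetle optimizer

Box-constrained minimization with a population split into four behavioral
roles (defaults: 30 % rollers, 30 % brood balls, 25 % foragers, 15 %
thieves; deflection k = 0.1, roll gain b = 0.3), iterating with the
shrinkage schedule R = 1 − t/Tmax:

* rollers:    `x ← x + α·k·x_prev + b·|x − Xw|`, α = ±1 equiprobable,
  Xw the current population worst;
* brood balls: `B ← X* + b1·(B − Lb*) + b2·(B − Ub*)`, b1, b2 ~ U(0,1)^D,
  confined to the spawning region around the current population best X*;
* foragers:   `x ← x + C1·(x − Lbb) + C2·(x − Ubb)`, C1 ~ N(0,1),
  C2 ~ U(0,1)^D, region around the best-so-far Xb, clipped to the box;
* thieves:    `x ← Xb + S·g·(|x − X*| + |x − Xb|)`, g ~ N(0,1)^D, S = 0.5.

Two printed-formula issues were resolved toward the algorithm's original
formulation.  First, the source prints the same scale factor for both bounds
of the spawning and feeding regions, which collapses each "region" to a
single point; the original uses (1−R) for the lower and (1+R) for the upper
bound, and that is implemented (the region is the coordinate box spanned
between anchor·(1−R) and anchor·(1+R) — span taken by min/max per coordinate
so negative coordinates behave symmetrically — intersected with the global
box, collapsing to the clipped anchor where empty).  Second, the stealing
behavior is listed in prose among the simulated behaviors but given no
equation; it is implemented from the original formulation and enabled by
default because without it the remaining three roles lack a late-run
exploitation operator and stall about an order of magnitude short on smooth
objectives (measured on the 3-D quadratic benchmark in the suite: median
best fitness ≈ 2.6e-2 without thieves vs ≈ 1e-4 with, at population 20 and
100 iterations over 10 seeds).  The "dancing" reorientation behavior has no
equation in any source used here and is not implemented; rollers can
therefore park on box faces, which the thief and brood stages compensate.
Other unpublished details, fixed once: fitness ties keep the earlier
incumbent; positions are hard-clipped after every update; Tmax = 0 returns
the best of the initial population.

## Hyperparameter tuning

DBO searches (log10 learning rate, hidden units, log10 L2) in
[1e-4, 0.1] × [5, 100] × [1e-4, 0.1] — the rates on log scale because the
ranges span three decades — with population 20 and 8 iterations by default;
hidden units are rounded at evaluation.  Fitness is the misclassification
rate of a model trained on 75 % of the training split and evaluated on the
remaining stratified 25 %.  The published protocol evaluates fitness on the
test set; that leaks the test split into model selection, so it is available
only behind `--paper-mode` and is off by default.

## Synthetic data

The generator (`chillgrade.synthetic`) emulates the qualitative pseudo-color
convention with full ground truth.  Leaf shape is a union of 1–3 random
ellipses; injury is accreted from random disks until the realized injured
fraction is within ±0.005 of target (the documented contract is ±0.02).
The grayscale raster is a fluorescence-yield field — healthy 180, injured 90,
background 0 gray levels, plus N(0, noise_sd²) noise — reflecting depressed
yield in injured tissue; the default noise_sd is 8 gray levels (≈ 3 % of
full scale, a mid-range speckle level for imaging assays), and
segmentation-accuracy guarantees are tested up to the documented cap of 25.
The pseudo-color raster is assembled in HSV: healthy hue in [0.95, 1]∪[0, 0.06]
(red), injury hue in [0.16, 0.33] (yellow-green), background V < 0.08, with
hue jitter clipped to its band so the bands stay disjoint at any noise level.
The default dataset is the study's stratified design: 42/46/46/42 training
and 10/12/12/10 test images per grade (176/44); per-class target ratios are
drawn uniformly inside each grade band, inset from the edges by more than the
realization tolerance so the realized grade always matches the requested
class.  `make_feature_table` is a fast tabular stand-in for classifier tests:
four unit-variance Gaussians whose means move monotonically with grade level
with a fixed sign pattern.

What passing on this data does **not** show: the synthetic bands are exactly
disjoint, so segmentation is near-perfect by construction and the end-to-end
accuracy on synthetic data (typically ≥ 95 %) says nothing about accuracy on
real PAM imagery, where pseudo-color palettes are smooth, venation and
specularity exist, and class boundaries blur.  The published dataset-level
accuracies are therefore not reproduced from images; the published confusion
matrices are used as worked examples for the evaluation module instead.

## Evaluation

Confusion matrices are actual-by-predicted counts.  Per class (one-vs-rest):
precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean; overall
accuracy is trace/total (the multiclass generalization of the published
binary form — it reproduces the published 86.36 and 95.45); summary
precision/recall/F1 are macro averages (unweighted over classes), which is
the averaging that reproduces the published metric table from its confusion
matrices.  Conventions: a never-predicted class has precision 0 (with a
warning); F1 is 0 when precision + recall is 0; display rounding is half away
from zero at 2 decimals, and published improvement deltas are differences of
the metrics at printed precision.

## Problem sizes used in the checked runs

The test suite and the acceptance script scale the expensive stages down:
64×64 images, DBO tuning with population 8 / 4 iterations / 40 epochs per
fitness evaluation, and 120 final training epochs.  These sizes were chosen
as the smallest at which every behavioral property is comfortably clear of
its threshold; the optimizer benchmark runs at full size (population 20,
100 iterations) and the worked-example and oracle checks are exact
computations at full precision.

## Known limitations

* Segmentation is thresholding only; it will not separate touching leaves or
  handle smooth pseudo-color palettes without re-tuning `SegmentationConfig`.
* The hue descriptor is an arithmetic mean of a circular quantity; for the
  red band straddling H = 0/1 the mean is convention-dependent.  It is kept
  arithmetic because the screening only consumes rank correlations.
* The numpy BiLSTM is full-batch and CPU-only; it is sized for hundreds of
  9-step samples, not for large imagery.
* DBO fitness evaluations retrain from a fixed seed; tuning noise from
  initialization is not averaged out.
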