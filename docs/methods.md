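# Methods

`pneumofuzz` implements a hybrid severity-scoring pipeline for pneumonia:
a capsule-network image classifier head whose softmax output is converted
into a calibrated confidence score, a Mamdani-style fuzzy inference engine
that fuses that confidence with 11 clinical symptoms, and a dynamic
adjustment algorithm that tracks per-patient symptom streams and adapts the
fuzzy membership bounds over time. This note records the model, its
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open.

## Image preprocessing

CLAHE splits the radiograph into a tile grid (default 8x8), clips each
tile's 256-bin histogram, and maps intensities through the scaled
cumulative sum; neighbouring tile mappings are blended by bilinear
interpolation between the four nearest tile centres, with clamped
replication outside the outermost centres. The clip limit (default 2.0) is
relative: the per-bin ceiling is `max(1, clip * tile_pixels / 256)`, the
convention of the mainstream library implementations. By default the
clipped excess is redistributed uniformly across bins; literal truncation
(no redistribution) is available via `redistribute_excess=False` for
equation-faithful testing, and its mapping is provably never brighter than
the redistributed one. After CLAHE the image may be resized to 224x224
(bilinear) and is normalized to [0, 1] by division by 255. Histogram
statistics use base-2 Shannon entropy (bits; 0 log 0 = 0), the image-texture
convention, so entropy lies in [0, 8] for 8-bit images. The CLAHE parameter
sensitivity sweep (clip {1, 2, 3} x tiles {4, 8, 16}) reports mean standard
deviation (contrast proxy) and mean entropy (texture proxy) per class, on
the CLAHE output at native resolution (before any resize).

Augmentation (rotation, shifts, shear, zoom, flips, brightness) draws each
transform uniformly within its configured range, uses bilinear resampling
with nearest-neighbour border fill, and is deterministic under a seed.

## Capsule head

A backbone feature tensor `F` (H x W x C) is refined by a 1x1 convolution,
reshaped into N primary capsules of dimension d (default 8) and squashed:
`v = (|u|^2 / (1 + |u|^2)) u / (|u| + eps)` with `eps = 1e-7`, which keeps
norms in [0, 1) and preserves direction. Dynamic routing to K = 3 class
capsules (dimension d', default 16 in the production config, 8 in the tiny
test model) runs 3 iterations by default with agreement logits initialized
to zero: couplings are the row-softmax of the logits (uniform 1/K on the
first iteration), class pre-activations are the coupling-weighted sums of
the prediction vectors `u_hat = u W`, outputs are squashed, and the logits
accumulate the scalar agreement `u_hat . v`. With one iteration the update
never fires, which is the configuration the equation-faithful tests use.
Class scores come from a dense ReLU head with dropout (disabled at
inference) over the flattened class-capsule matrix — capsule norms are
deliberately *not* used as class probabilities.

The trainable `TinyCapsNet` (two 3x3 stride-2 conv layers, ~25k
parameters) exists to exercise this math end to end on 32x32 phantom
images; its backward pass is hand-derived, with gradients flowing through
the prediction vectors and squash Jacobians while the routing couplings
are treated as constants (stop-gradient), the standard practice for
dynamic routing. Training uses Adam with shuffled minibatches, early
stopping after 5 non-improving epochs, and learning-rate halving on
plateau; it is deterministic under a seed and reaches 100% training
accuracy on 30 separable phantoms within 50 epochs. Grad-CAM pools the
logit gradient over the second conv activation, ReLUs and min-max
normalizes the weighted sum, upsamples bilinearly, and binarizes with
Otsu's threshold on the 256-bin heatmap histogram; a constant heatmap has
no Otsu separation and maps to an all-background mask.

## Calibrated confidence

For a probability vector `p` over (Normal, Abnormal, Pneumonia):
margin `M = p_top1 - p_top2`; entropy `H = -sum p_i ln(p_i + 1e-12)`
(natural logs — any consistent base cancels in the normalization
`H_norm = H / ln 3`); calibrated score `C = p_top1 * M * exp(-H_norm)`;
class weight `lambda = softmax(r)[argmax p]` with relevance scores
`r = (0.25, 0.50, 0.75)` mapped to (Normal, Abnormal, Pneumonia) in order
of clinical urgency (configurable — this class-order mapping is the one
genuine ambiguity in the scheme); contribution
`Confidence = 100 * lambda * C`. A uniform vector scores exactly zero; a
one-hot vector approaches `C = 1` and `Confidence = 100 * lambda`.

## Fuzzy severity engine

The 11 inputs (eight 0-1 symptom scales, fever 35-42 degC, SpO2 80-100 %,
fever duration 0-30 days) are min-max normalized. Grading happens on a
*severity-aligned* axis: for oxygen saturation, whose low end is the severe
direction, the graded value is `1 - theta`. This keeps the Poor / Average /
Good categories uniformly meaning "low / intermediate / high severity
evidence", which is what makes the engine's monotonicity guarantee (below)
possible.

Membership functions are piecewise linear: Poor is 1 on [0, 0.2] falling
to 0 at 0.4; Average rises from 0.2 to a plateau on [0.4, 0.6] and falls
to 0 at 0.8; Good rises from 0.6 to 1 at 0.8. The crossovers sit at
exactly 0.3 and 0.7 with grade 0.5, matching the crisp category table
(Poor below 0.3, Average up to 0.7, Good above). Rules combine antecedent
grades with the standard Mamdani t-norms — AND is min, OR is max — and
carry weights of +10 (AND) and +5 (OR), overridable per rule. Aggregation
is a weighted **sum** of activations (the only reading consistent with the
0-40+ severity bands; a max-of-activations mode is available), both per
severity class (`R_c`) and in total (`mu_Severity`); defuzzification is
the weighted average `S_fuzzy = mu_Severity / sum(w_k)` in [0, 1].

Severity bands: score < 10 Negligible, [10, 25) Mild, [25, 40) Moderate,
>= 40 Severe. The assessment reports bands for the total `mu_Severity`
(the headline, since the +10/+5 weights set that scale), the winning
class's raw score, and the literal fused scalar. With a dense rule base
the total saturates toward Severe sooner than the per-class view; the
per-class scores are the more informative output and drive the label.

Confidence fusion has two modes. The default `argmax` mode adds the
confidence contribution to the severity class mapped from the predicted
image class (Normal -> Negligible, Abnormal -> Moderate, Pneumonia ->
Severe, configurable) and labels by argmax over adjusted scores, ties
broken toward the more severe class (clinically conservative); a score
vector that is entirely zero labels Negligible, since no finding and no
confidence is the absence of disease, not a tie. The `literal` mode adds
the confidence directly to the defuzzified scalar, which mixes a 0-1
quantity with a 0-~42 one — it is kept because it is the written fusion
rule, but the argmax mode is the one consistent with per-class score
margins. A case is **borderline** when the top-two adjusted scores differ
by at most 2.0 points *and* both are positive: the flag describes a
genuine contest between two activated severity levels, so neither an
all-zero vector nor a single weak activation qualifies.

### The default rule base

The shipped rule base (JSON, editable) is illustrative, not clinically
validated. It contains the two canonical example rules (a three-antecedent
AND rule for Severe and an appetite/fever OR rule for Moderate) plus
per-symptom ladder rules: Average-antecedent singletons feeding Mild or
Moderate and Good-antecedent singletons feeding Severe, with two weight
overrides (20 for fever-good, 15 for appetite-good). The structure is
deliberate on two counts:

* **Monotonicity.** Raising any symptom on the severity-aligned axis never
  lowers `mu_Severity`. Every falling membership slope introduced by an
  Average or Poor antecedent is compensated by a rising rule of at least
  equal weight on the same symptom — that is what the two weight overrides
  are for. The property is enforced by a randomized test.
* **Genuine middle-class competition.** Average-severity findings are split
  between Mild and Moderate consequents, so cases in the ambiguous middle
  produce two comparable class scores and the <= 2.0 margin actually
  fires there, while Negligible cases (no activation) and Severe cases
  (landslide scores) are not flagged. This reproduces the qualitative
  behaviour the experiments target: the DL confidence matters exactly
  where the fuzzy evidence is ambiguous.

## Dynamic membership adjustment

Per symptom stream, in order: (1) Z-score filtering drops points more than
3 population standard deviations from the full-series mean (zero spread
drops nothing); (2) recent mean and population variance over the last 10
points (all, if fewer); (3) smoothing factor `S = min(1, 0.3 +
variance/100)` — the cap is needed because on raw clinical scales
(fever-duration variance runs to hundreds) the uncapped value would break
the convexity of the recursion; (4) exponential smoothing
`out[i] = S x[i] + (1 - S) x[i-1]` against the previous **raw** value — an
unusual but deliberate recursion, kept literal with the classic EMA as an
option, the two differing from the third point onward; (5) percentile
thresholds (10, 90) when the recent mean, taken on the normalized scale so
the 0.5 pivot is meaningful for non-unit symptoms, is <= 0.5, else
(15, 85) — the boundary value goes to (10, 90); (6) the adjusted bounds
are those linear-interpolation percentiles of the smoothed series, gridded
in 0.1 steps on the raw clinical scale; (7) clipped to the clinical
bounds.

Stabilization diagnostics feed a stream point by point, recompute bounds
at every iteration (so each iteration's bounds reflect the previous
updates), and summarise at checkpoints (10, 20, 30, 50, 100): the
per-iteration percent changes of each bound within the window since the
previous checkpoint give a per-symptom mean and population standard
deviation (a step whose previous bound is ~0 is skipped as undefined).
The initial (first-checkpoint) and final (last-checkpoint) min/max means
combine into `Initial` and `Final` averages, the stabilization factor
`SF = max(0.4, 1 - Final/Initial)`, and the fluctuation reduction
`F = (Initial - Final)/Initial * 100`; symptoms still fluctuating more
than 1% at the last checkpoint are flagged for further stabilization. A
zero initial average leaves SF and F undefined (reported as an error, not
a number). The 0.4 floor doubles as the damping that prevents the factor
from collapsing when fluctuation grows.

## Synthetic data

The generators exist so every stage is testable offline; they emulate
class-conditional classifier outputs, severity-conditioned symptom cases,
drifting symptom streams, and blob-bearing phantom images — not realistic
radiographic texture, label noise, inter-observer variability, or
correlated symptom physiology. Passing tests therefore demonstrate the
pipeline's mathematical and behavioural contracts, not clinical validity.

Case generation samples each symptom uniformly from class-conditional
intervals (Negligible: unit symptoms U(0, 0.2), fever U(36, 37.2), SpO2
U(95, 100), duration U(0, 2); Severe: U(0.75, 1), U(39, 41.5), U(80, 88),
U(7, 21); Mild and Moderate interpolate the endpoints at 1/3 and 2/3) and
couples a classifier vector: Negligible cases look Normal (bias 0.9),
Severe cases look like Pneumonia (0.9), the middle is ambiguous Abnormal
(0.65) — radiographically clear at the extremes, uncertain in between.
Streams are linear trends on the severity axis plus Gaussian noise
(default sd 0.25 for the stabilization study) with rare in-bounds extreme
outliers (rate 0.05), clipped to clinical bounds. Phantoms are 32x32:
gradient-plus-lung-fields backgrounds, bright Gaussian blobs for
Pneumonia (centroids recorded for localization checks), ring/line
artifacts for Abnormal.

## Experiments and problem sizes

The borderline experiment generates 300 cases (75 per category), assesses
each with and without its classifier vector (the fuzzy-only branch never
reads the vector), flags borderline cases under either setup, and emits
the per-class score differences. The stabilization experiment runs
100-iteration streams for all 11 symptoms. The test suite trains the tiny
capsule model once on 30 phantoms and reuses it; CLAHE oracle comparisons
run on 64x64 images with 2x2 tiles, and the calibration oracle sweep uses
1,000 random simplex points. These sizes keep the full suite under about
ten seconds on one CPU while exercising every contract.

## Known limitations

* The default rule base is illustrative; no clinical claim attaches to it
  or to the class-conditional generator intervals.
* The capsule model's stop-gradient routing means training gradients are
  approximate with more than one routing iteration (the forward pass is
  exact in all cases).
* The literal fusion mode mixes scales, as written; prefer `argmax`.
* Percentiles in the adjustment are taken over the full retained series,
  not only the recent window; with long histories the bounds respond
  slowly to regime changes.
* DICOM ingestion, colour images, and dataset-scale training pipelines are
  out of scope.
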