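# Methods

This note records what `hbscreen` computes, the assumptions behind the
synthetic data, the parameter choices that matter, and where the design
was genuinely open.

## The screening problem

A stained cellulose-acetate strip carries up to eight patient lanes.
Within a lane, haemoglobin variants separate along the migration axis:
HbA travels furthest from the application point, HbF less far, HbA2
least. Band darkness is proportional to the variant's share of total
haemoglobin. Normal adults show a dominant HbA band and a faint HbA2
band (< 3.5 % of total stain); beta-thalassaemia-trait carriers show an
elevated HbA2 band (up to ~7 %), sometimes with mild HbF. The package
turns a scanned strip into per-patient class decisions.

Conventions, stated once and used everywhere: images are `[row, col]`
arrays, migration runs along rows with the application point at row 0,
lanes sit side by side along columns, coordinates are 0-based and boxes
half-open.

## Synthetic strips

No public image set of this modality exists, so the generator is a
first-class, tested component, and its defaults define the study
conditions used by the tests and the acceptance script.

**What it emulates.** A pink Ponceau-like background (RGB 247/214/220)
with dark-red bands (135/22/58) rendered as 1-D Gaussians along rows
(FWHM = `width_frac` × strip height) times a flat-top lane window with a
2 px cosine roll-off across columns. Integrated band darkness is
proportional to `intensity_frac` with gain 60, so a dominant HbA band
saturates (clips at darkness 1) the way heavily stained bands do.
Band positions are fixed at fractions 0.72 (HbA), 0.52 (HbF), 0.32
(HbA2) of the migration axis. Class-conditional composition: normal
lanes draw HbA2 ~ U(0.015, 0.030); carrier lanes draw
HbA2 ~ U(0.040, 0.070) and add an HbF band (U(0.03, 0.12)) with
probability 0.35; HbA takes the remainder. The 3.5 % HbA2 cutoff is the
label definition and is enforced as an invariant.

**Nuisances.** Additive Gaussian pixel noise (default sd 3 gray
levels), a linear illumination gradient along the migration axis
(default 0.015 gray/px ≈ 19 levels over the strip), lateral lane jitter
(±3 px), and — with probability 0.1 per adjacent pair — a *merged*
pair: the two lanes are pulled to a 1–3 px gap and their HbA bands are
connected by a ~5-row-tall stain-bleed bar (darkness 0.5). Default
canvas: 1280 rows × 320 columns for 8 lanes.

The merged-lane geometry is a deliberate design decision. If two lanes
are merged by overlapping their full-height band blobs, the seam
between them is interior foreground — never within any bounded distance
of background — so *no* opening of bounded radius can split it;
erosion-based separation is provably impossible on that geometry. A
thin bleed bar at the band rows is both closer to what bleeding between
neighbouring samples looks like and exactly the failure mode a
two-scale opening can repair: the cumulative radius-3 erosion
(3×3 then 5×5) removes a ≤ 6-row bridge, while a single 5×5 pass
(radius 2) leaves a one-row remnant that the compensating dilation
would regrow into a reconnecting line. The two scales are therefore
load-bearing, not decorative.

**What it does not emulate.** Scanner optics, stain batch variation,
curved lanes, within-band texture, or quantitative densitometry.
Passing tests on synthetic strips therefore demonstrate that the
algorithms are implemented correctly and behave sensibly under the
modelled nuisances — not that the classifier's synthetic accuracy
transfers to real strips.

## Lane extraction

Pipeline: BT.601 grayscale → complement (bands become the bright
minority) → 5×5 Gaussian (σ = 1.0, reflected borders) → Otsu threshold
computed on the *blurred* complement → binarize (foreground = pixels
> t) → two-scale opening → 8-connected components → lane boxes → crop
and bilinear resize to 150×30×3.

Choices that were open and how they were fixed:

- **σ = 1.0** for the 5×5 kernel: ±2σ spans the kernel support.
- **Otsu on the blurred complement** rather than the raw complement:
  single-pixel noise cannot shift the histogram valley. Ties in the
  between-class variance break toward the smallest threshold, and the
  implementation is verified against an exhaustive 255-threshold scan
  on every test image. A constant image raises an explicit
  degenerate-histogram error.
- **Erosion scales 3×3 then 5×5, one compensating 5×5 dilation** — the
  smallest standard pair bracketing a 5×5 element (see the bridge
  arithmetic above).
- **min_area = 0.05 %** of image pixels rejects stain specks; being
  relative, it keeps behaviour stable when the strip is rendered at
  another resolution.
- **Lane box = full strip height over a component group's column
  extent** (bands of one patient stack vertically and share a column
  interval), padded by 2 px and clipped; column intervals closer than
  2 px are grouped. Boxes come back strictly left-to-right.
- When the detected lane count differs from `expected_lanes`, a
  structured warning is attached — never silently fixed. An optional,
  off-by-default fallback can split the widest box into equal parts.
- Border rule: out-of-image pixels count as background for both erosion
  and dilation, so erosion/dilation duality holds exactly on the
  interior (tested there) but not on the 1-px frame.

## Augmentation

Each training image yields itself plus 14 variants; variant *k* applies
one strategy, cycling rotation → scale → translate, with its parameter
drawn uniformly from the stated range (rotation 3–5° clockwise,
magnification 2.5–10 %, translation 5–10 % of each image dimension,
horizontal and vertical, random sign). One strategy per variant
reproduces the 15× cardinality without inventing composite transforms.
Outputs keep the 150×30 geometry (border replication); all parameters
are logged in each variant's metadata; augmentation happens strictly
after fold splitting and only on training ids.

## Classification harness

Stratified five-fold rotation over a seeded per-class shuffle: per
class, fold *f* tests the *f*-th contiguous block of ⌊n/5⌋ shuffled
ids (the remainder is never tested), a fixed validation count is taken
from the rest, and the remainder trains. At the 262-per-class reference
scale this yields 52/21/189 test/validation/training per class per
fold; the validation size follows the tabulated protocol (21 ≈ 10 % of
the non-test ids) rather than a 20 %-of-training reading, since only
the former reproduces the 189-training count.

Training: softmax cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999) at
learning rate 10⁻³, batch 16, ≤ 15 epochs. An epoch "improves" when
validation loss is strictly below the best seen; after 4 consecutive
non-improving epochs the learning rate is multiplied by 0.1 (the factor
is our choice; only the patience is prescribed), after 5 training
stops, and the best-validation-loss weights are restored. All
randomness (shuffles, init) flows from explicit seeds; reruns are
bit-reproducible.

The network stack is implemented in numpy (im2col convolution, max
pooling, linear head, Adam) and exposes named activations so Score-CAM
can read feature maps. `tinycnn` — conv(3→8)/ReLU/pool2,
conv(8→16)/ReLU/pool3, flatten, linear — is the bundled architecture
(~5.4 k parameters, seconds per fold on one CPU). The registry reserves
the names of the seven standard ImageNet architectures for externally
registered builders; constructing them without one raises a clear
error rather than silently substituting.

**Input normalization** is per-image standardization (zero mean, unit
variance over all pixels and channels) rather than plain [0,1] scaling.
The discriminative signal — the darkness of a faint HbA2 band — is a
small offset on a dominant background; standardization removes
per-lane illumination and background-tint variation and measurably
stabilizes training (pooled CV accuracy on the well-separated surrogate
moves from ~92 % to 100 %).

## Evaluation

From the pooled confusion matrix (positive class = thalassaemia):
accuracy on pooled counts; recall, specificity, precision and F1 per
class, macro-averaged as the unweighted two-class mean. Zero
denominators yield NaN markers, never exceptions. Each percentage
carries the 95 % normal-approximation half-width
r = z·√(m(100−m)/N), z = 1.96, in percentage points. **N convention**:
the pooled test count for accuracy and the per-class count for the
class-conditional metrics — this is the unique assignment that makes
the reference half-widths (±1.72 at N = 524 vs ±2.42/2.43 at N = 262)
internally consistent, and it is documented here as reverse-engineered
rather than externally specified. ROC curves come from a full threshold
sweep with half-credit ties (Mann–Whitney equivalence, verified against
an all-pairs oracle); per-fold curves are vertically averaged on a
fixed 101-point FPR grid. Per-image elapsed time (t₂−t₁)/n is reported
for information only — timing depends on hardware and is never asserted
against any reference value.

## Score-CAM

For the chosen convolutional activation (default: the last one), each
channel is min-max normalized, bilinearly upsampled to the input size,
and multiplied elementwise with the (standardized) input over a zero
baseline; the masked input's softmax score for the target class is the
channel weight (raw score, no softmax over channels). The map is the
rectified weighted sum, min-max normalized; all-zero activations give
the all-zero map. On trained synthetic classifiers the mean saliency
on band rows exceeds the off-band mean — asserted only on synthetic
data.

## Problem sizes used by the tests and the acceptance script

The test suite and `scripts/acceptance.py` run entirely on synthetic
data: 100 default-condition strips (800 lanes) for the lane-recovery
property; ~400 well-separated lanes (50 clean strips, HbA2 ~1 % vs
~7 %, noise sd 1, no merging) for the five-fold CV surrogate, run
without training-set augmentation (the 15× cardinality is verified
separately, and the easy separation does not require it); 189 lanes for
the augmentation arithmetic; ≥ 200 random instances per oracle-
equivalence property. These sizes keep a full run to a few minutes on
one CPU while leaving each property comfortably over-determined.

## Known limitations

- The synthetic renderer is a geometric/photometric idealization; no
  claim about real-strip accuracy follows from it.
- Only the binary normal vs beta-thalassaemia-trait decision is
  modelled; severity grading and other haemoglobinopathies are out of
  scope.
- Pretrained ImageNet backbones are not bundled; the harness is
  architecture-agnostic but ships only `tinycnn`.
- Band-level densitometry (an explicit HbA2 percentage) is not
  computed; the classifier consumes whole lane images.
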