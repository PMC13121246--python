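# Methods

`drgrade` implements an explainable five-class grader for diabetic
retinopathy (DR) fundus photographs on the International Clinical
Diabetic Retinopathy (ICDR) scale: 0 No DR, 1 Mild, 2 Moderate,
3 Severe, 4 Proliferative. A case of grade 2 or higher is *referable*
(requires specialist review). This note records the model, the data
protocol, the numerical choices, and what the desk-scale tests do and do
not establish.

## Dataset assembly protocol

Real five-grade fundus datasets are heavily imbalanced (the most
populated class can exceed the rarest by a factor of 30). The assembly
pipeline mirrors the protocol of the study the package operationalises:

1. **Per-class capping.** Classes with more than `per_class_cap`
   (default 150) source images are uniformly subsampled to the cap.
   Fully balancing the rarest class (35 images) up to the largest (1017)
   by augmentation alone would require (1017−35)/35 ≈ 28.1 artificial
   images per real one; capping keeps the artificial fraction sane.
2. **Split before augmentation.** A stratified 80/20 train/validation
   split is drawn *before* any augmentation, so no two images derived
   from the same source can land on opposite sides of the split.
   Validation size is `round(0.2·n)` with half-up rounding
   (35 → 28/7, 150 → 120/30).
3. **Auxiliary merging.** Compatible images from a second acquisition
   campaign join the *training* split only, with per-class quotas
   (default {40, 40, 40, 70, 80}). Compatibility is decided visually at
   paper scale; here it is operationalised as: the foreground is a full
   circle of diameter ≥ 0.95·min(H, W) touching no frame border, and a
   bright, approximately square mark of side 1–5 % of the width sits in
   the first (top-right) quadrant. The 0.95 and 1–5 % thresholds are
   package choices; only the visual rule is given.
4. **Balancing augmentation.** Training classes below
   `train_class_target` (default 160 = 120 originals + 40 auxiliary of a
   populated class) are topped up with randomly perturbed copies of
   train-split source images: horizontal flip (p = 0.5), rotation
   uniform in ±10°, per-channel integer shift uniform in ±10 gray
   levels. Rotation fills exposed corners with black (the fundus
   background); auxiliary images are never used as augmentation parents.
   For the rarest class this yields 160 − (28 + 80) = 52 augmented
   images, 32.5 % of its training pool.
5. **Blend expansion.** Every record, training and validation, is
   replaced by three enhanced variants (below), tripling the static
   dataset: 160 → 480 train, 30 → 90 validation per populated class.
6. **Dynamic augmentation.** During training each static record is
   freshly perturbed once per epoch: a 30-epoch run visits
   480 × 30 = 14 400 training and 90 × 30 = 2 700 validation images per
   populated class.

Derived records are *lazy*: an augmented or blend record stores only its
parent id; pixels are regenerated on demand from a per-record seed
(CRC32 of the record id mixed with the stage seed). This keeps all
accounting recomputable from the manifest CSV alone, and makes
identically-seeded assemblies byte-identical.

## Preprocessing

Images are cropped to the largest centered inscribed circle (pixel-center
test, 0-based row/column coordinates) and resized square with plain
bilinear interpolation under an explicit pixel-center convention
(`src = (dst + 0.5)·scale − 0.5`). The enhancement is the weighted
Gaussian blend widely used for retinal images:

    out = clip(α·I + β·G_σ(I) + γ, 0, 255),  α = 4, β = −4, γ = 128

a high-boost filter that removes slow illumination gradients and
amplifies vessels and small lesions. The three σ values default to
side/60, side/30 and side/15 so the variants scale with resolution;
no canonical values exist for them, and the blend coefficients are the
conventional competition values, both configurable in `BlurSpec`.

## Synthetic data generator

The generator renders a circular reddish-orange fundus field on black
with branching vessel strokes and a bright optic disc, then draws the
lesions that define each ICDR grade, recording every lesion (type,
center, radius, quadrant) as ground truth:

| grade | microaneurysms | haemorrhages | hard exudates | soft exudates | proliferative signs |
|------:|---------------:|-------------:|--------------:|---------------|---------------------|
| 0     | 0              | 0            | 0             | —             | — |
| 1     | 1–3            | 0            | 0             | —             | — |
| 2     | 8–15           | 2–5          | 2–6           | 0–1 quadrants | — |
| 3     | 16–24          | 8–12         | 4–8           | 2–4 quadrants | — |
| 4     | 18–28          | 12–16        | 4–8           | 2–4 quadrants | 3–5 neovascular strokes, 1–2 preretinal haemorrhages |

Grades 3–4 place the first four microaneurysms and haemorrhages
round-robin across the four quadrants, so "lesions in all quadrants" is
guaranteed by construction. Lesion renderers are simple parametric
primitives (anti-aliased disks, Gaussian blobs, random-walk strokes);
grade 4 additionally carries a large dark preretinal-haemorrhage blot, a
hallmark of proliferative disease. Lesion sizes scale linearly with the
image side and were chosen once so that each grade's signature remains
resolvable at the backbone input resolution — by design the generator
must produce a *learnable* grade structure, not photorealism. Auxiliary
images are emulated by a pure-white square mark near the rim in the
first quadrant (everything else is clipped below white so the mark is
unambiguous); incompatible images by a fundus wider than the frame.

What the generator does **not** emulate: camera noise and optics, label
noise, anatomical variation (macula, tessellation), lesion appearance
diversity, co-occurring pathology. Desk-scale results therefore show
that the pipeline's machinery is correct and that the protocol is
learnable end to end — they say nothing about accuracy on real fundus
photographs.

## Ensemble and backbones

The classifier is a parallel ensemble of two convolutional members
behind an abstract contract (5-way logits plus named convolutional
feature maps with class-score gradients). Member outputs merge as the
arithmetic mean of their softmax probabilities, renormalized; a
logit-space mean is available as a configurable alternative
(`combine(..., mode="mean_logit")`). The prediction carries the
probability-ranked classes (ties break toward the lower, milder grade)
and the quality factor

    Q = round(p₁ / p₂) clamped to [1, 99]   (p₂ = 0 → 99)

over the top-2 combined probabilities — an integer confidence indicator:
Q = 1–2 flags a borderline case for expert review. Under the logit-mean
combination rule the same ratio equals exp(z₁ − z₂) on the combined
pre-softmax scores.

No deep-learning framework is assumed: the two reference members are
tiny CNNs built on an in-package numpy engine (im2col convolution,
ReLU, 2×2 max pooling, concatenated global average+max pooling, dense
head, Adam, manual backprop verified against numerical gradients).
Member A is a plain four-block net with one explanation layer; member B
computes its logits as the *sum of two heads* attached at different
depths, so it exposes two target layers and its explanation is the
average of two Grad-CAMs. The average+max pooled head matters on this
task: the average channel integrates lesion load, while the max channel
detects the presence of a single small lesion, which separates the
earliest grades. Paper-scale backbones attach through the same contract.

Training is plain cross-entropy with Adam (lr 10⁻³–3·10⁻³, conventional
and config-exposed since no canonical values exist), each member trained
independently on the dynamically augmented stream, fully seeded; equal
seeds reproduce weights and logs bit-for-bit.

## Explanation and report

Grad-CAM at a target layer: channel weights are the spatial means of the
class-score gradient, `L = ReLU(Σ_k α_k A^k)`, bilinearly upsampled to
the image and min-max normalized to [0, 1]; an identically-zero rectified
map stays zero (normalization choice — none is canonical). Dual-stage
members average their two stage maps; the ensemble heatmap averages the
member maps, both at image resolution before re-normalization (members
may differ in input side). The clinician report lists the top-2
diagnoses with probabilities and Q, flags Q ≤ 2 as low confidence, and
renders a configurable panel selection (default: the ensemble average,
labelled "M: 0"; individual members "M: k") using a perceptually uniform
colormap over an alpha blend.

## Evaluation

Per class c, one-vs-rest counts give accuracy, specificity, precision,
sensitivity and F1 (harmonic mean); these are reported per class plus
their unweighted macro means — summing the per-class ratios directly
would exceed 1, so the one-vs-rest reading with the multiclass headline
accuracy trace(confusion)/N is the only consistent one. Metrics with a
zero denominator are undefined (NaN), excluded from macro means, and
logged. AUC is the trapezoidal area under the threshold-swept ROC curve,
identical to the Mann–Whitney statistic with half credit for ties
(scikit-learn provides the curve; tests verify the pair-counting
identity to 1e-12). Referable-DR scores sum the grade ≥ 2 probabilities.
Five-fold cross-validation folds only source-origin records, keeps
auxiliary records in every training split, and flags the worst fold
(lowest accuracy, ties by lowest macro AUC). The evaluator also reports
the fraction of errors that are one grade off (adjacent-error fraction);
it is reported, not asserted, since its value is an empirical property
of a trained model.

## Desk-scale study sizes

The canonical in-repo study (`drgrade.pipeline.run_desk_scale`, also run
by `scripts/acceptance.py` and the test suite) uses 100 synthetic images
per class rendered at side 256, capped/split/blend-expanded with the
protocol above (no auxiliary pool — synthetic data is already balanced),
a two-member ensemble at 96 px input, batch 8, learning rate 3·10⁻³,
10 epochs of dynamic augmentation. These sizes are the package's chosen
desk-scale study conditions; at them the ensemble reaches ≥ 90 %
validation accuracy with errors almost exclusively between adjacent
grades, and the ensemble Grad-CAM concentrates inside lesion ground
truth on most proliferative images.

## Known limitations

- The numpy backbones are minimal by design; they demonstrate the
  contract, not competitive accuracy, and are CPU-bound beyond desk
  scale.
- The synthetic task is far easier than real fundus grading; absolute
  metric values do not transfer.
- The compatibility filter encodes one acquisition campaign's visual
  signature; other auxiliary sources would need their own rule.
- Binary (referable) evaluation is derived by thresholding the 5-class
  model's summed probabilities; retraining a dedicated two-class model
  is supported by the same pipeline but not exercised in the tests.
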