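# Methods

This note documents the models, procedures and design choices behind
`spiroqc`, in the order the pipeline runs them.

## Problem setting

Spirometry quality control hinges on visual inspection of the flow-volume
and volume-time curves printed on the spirometer's report: a cough, an
early termination, a submaximal effort or an extra breath invalidates the
maneuver. `spiroqc` automates this inspection. It turns the report page
plus three demographic fields (sex, age, BMI — variables known to
correlate with maneuver quality) into a single "graphical construct"
image, scores the risk that the maneuver is unacceptable with a
convolutional classifier, selects the decision threshold by maximizing
the Matthews correlation coefficient (MCC), and explains each decision
with a Grad-CAM heatmap.

Clinical spirometry reports are not redistributable, so the package ships
a synthetic report simulator that emulates the relevant features of such
data; everything downstream is agnostic to whether a page is synthetic or
real.

## Synthetic maneuvers (`spiroqc.simulate`)

The clean forced-expiration flow profile is a quarter-sine rise to peak
flow followed by an exponential decay,

    f(t) = PEF · sin(π t / (2 t_rise))     t ≤ t_rise
    f(t) = PEF · exp(−(t − t_rise)/τ)      t > t_rise,

rescaled so the time integral of flow equals the requested FVC. This is a
deliberately minimal model: it has two clinically meaningful knobs (PEF
in L/s, FVC in liters), produces realistic-looking flow-volume loops, and
every derived quantity has a closed form, so the generator can be checked
against independent quadrature. Default parameter ranges — FVC in
[2.5, 5.5] L, PEF in [5, 10] L/s, rise time in [0.08, 0.15] s, decay
constant τ in [0.5, 0.9] s, duration max(6, 6τ) s — cover typical adult
maneuvers. The sampling step is 5 ms.

Artifacts are injected as perturbations of the clean series, each with a
recorded time interval:

- **cough** — a pair of opposite-sign Gaussian flow lobes (default
  amplitude 0.5·PEF, half-width 0.08 s) centered at a random onset in
  the last third of exhalation; the perturbation is truncated to exactly
  zero outside onset ± 3 widths, so the series equals the clean one
  outside the annotated interval bit for bit.
- **early termination** — the series is cut where exhaled volume reaches
  a truncation fraction of FVC, drawn uniformly from [0.5, 0.85].
- **submaximal effort** — flow globally scaled by 0.7 and the peak
  flattened at 0.85 of the scaled maximum.
- **extra breath** — a negative-flow half-sine (inhalation; 0.4 s,
  0.3·PEF) spliced into the series, time-shifting the remainder.

Any artifact makes the ground-truth label *unacceptable*; a clean
maneuver is *acceptable*. Artifact frequencies in generated datasets are
uniform across the four types — no clinical frequency data informs them.

### Report rendering

Pages default to 1000 × 1400 px (portrait, ~150 dpi letter-ish). The
demographics are printed as labeled text lines in the top half
(`Sex: …`, `Age: …`, `BMI: …`); the volume-time plot renders in the
bottom-left box and the flow-volume plot beside it, both strictly in the
bottom half. Pre-bronchodilator curves are pure blue, 4 px strokes; an
optional post-bronchodilator overlay (a weakened copy of the maneuver,
drawn underneath) uses pure red by default, with pink/maroon variants
available through the layout to exercise the color mask's tone range.
The artifact's time interval is mapped to a pixel bounding box on the
plot where it is visible (volume-time for early termination, flow-volume
otherwise); this annotation is what the Grad-CAM localization check uses.

The simulator makes no claim of population realism: demographics are
uniform over the encoder's bounds with a fair sex split, curve colors and
layout are idealized, and there is no scanner noise, skew or vendor
typography. Passing tests therefore show that the pipeline's mechanics
are correct under controlled conditions, not that the classifier
generalizes to any specific spirometer's reports.

## Ingestion (`spiroqc.ingest`)

Raster reports (PNG/JPEG) pass through unchanged; grayscale images are
promoted to three identical channels. For PDFs, only image-based files
(one full-page embedded image per page — what Pillow and scan-to-PDF
tools produce) are supported: a minimal reader extracts and decodes the
first page's image XObject. Vector-drawn PDFs are out of scope because
the package bundles no PDF rasterizer.

Demographics are parsed from labeled text lines with a small grammar:
case-insensitive label synonyms (sex/gender/sexo, age/edad, bmi/imc),
`:`-separated values, decimal commas tolerated, unit suffixes ignored,
sex tokens man/male/hombre and woman/female/mujer. A sidecar CSV
(`path,sex,age,bmi`) substitutes when the report has no text layer.
Missing fields raise an error naming the field.

## The graphical construct (`spiroqc.construct`)

Stage 1 isolates the curves:

1. **Color mask.** Pixels whose HSV hue lies within ±20° of red with
   saturation ≥ 0.20 and value ≥ 0.20 are set to white. This covers pure
   red, maroon (dark red) and pink (desaturated red) while leaving blue
   curves and black text untouched. The saturation floor sits at 0.20
   because classic pink (255, 192, 203) has saturation ≈ 0.247 and
   anti-aliased pink edges fall lower still.
2. **Grayscale + crop.** Fixed luma weights (0.299/0.587/0.114); only
   rows from the page's vertical midpoint down are kept.
3. **Binarize + invert.** Otsu's threshold (parameter-free, robust to
   rendering contrast); foreground = darker than threshold, so curves
   become white on black.
4. **Noise filter.** Connected components with area *strictly less than*
   1000 px are discarded. The boundary is exact: a 1000-px region
   survives. The threshold is configurable since its right value couples
   to rasterization dpi.
5. **Closing.** 5 × 5 square structuring element — enough to fill
   single-stroke gaps left by the mask where the red curve crossed the
   blue one, without merging the two curve regions at the default
   geometry.
6. **Selection.** 8-connected labeling; regions sorted by area
   descending, ties broken toward the leftmost-topmost bounding box
   (logged); the two largest are kept, and identified as volume-time /
   flow-volume by horizontal position (volume-time leftmost under the
   default layout — area ordering alone cannot tell the curves apart).

Each crop is scaled preserving aspect ratio into a 350 × 500 sub-panel
(bilinear, re-thresholded at 128 to stay binary) and centered:
volume-time in rows [0, 350), flow-volume in [350, 700), forming the
700 × 500 panel. "700 × 500" is read as rows × columns: the demographic
frame is appended *to the right*, which only yields the 700 × 700 square
if the width is 500.

Stage 2 encodes demographics. Age is min-max normalized over [10, 84]
years and BMI over [15, 54] kg/m²; sex maps man → 0, woman → 1. Values
outside the bounds are clamped with a logged warning. The 200-column
frame is split into three near-equal sections — sex rows [0, 234), age
[234, 467), BMI [467, 700), top-to-bottom (700 is not divisible by 3;
the first section absorbs the extra row) — each filled with the constant
gray round(v·255), rounding half up. The worked example (woman, 45 y,
BMI 18.1) gives grays 255 / 121 / 20.

Finally the 700 × 700 square is resized to 224 × 224 (bilinear,
anti-aliased, values kept on [0, 255], rounded to uint8) and replicated
to three identical channels. The construct object retains all
intermediates and can map any page-pixel box through crop, scaling,
placement and resize into network-input coordinates.

## Classifier (`spiroqc.net`, `spiroqc.model`)

The classifier is a compact convolutional network written directly on
numpy, with explicit forward and backward passes (convolutions as sums
of strided tensor contractions over kernel offsets, verified against
central-difference gradients). Architecture: four conv/ReLU blocks
(1→8→16→32→32 channels, kernel 5 then 3s, all stride 2), concatenated
global **average + max** pooling, and a 2-class linear head. At 224 × 224
input the feature grid is 14 × 14. The avg/max concatenation matters: a
cough is a localized anomaly occupying a few feature cells, and a plain
spatial average dilutes it ~200-fold, which in practice stalls training
at the class prior; the max path makes the localized signal linearly
accessible, while the average path serves curve-wide cues (submaximal
effort, early termination). Training is from random (He) initialization
— no pretrained weights ship with the package.

Inputs are standardized as gray/255 − 0.5. Training minimizes 2-class
cross-entropy with Adam under the reference configuration: mini-batch
64, learning rate 1e-4, up to 100 epochs, validation once per epoch,
early stop after 20 consecutive evaluations without improvement, and the
returned parameters are those of the best-validation evaluation. (The
reference learning rate suits fine-tuning; the from-scratch experiment
below passes 3e-3.) Splits are stratified — test 10%, then an absolute
validation count (23 by default, a fraction if < 1) from the remainder —
so both classes appear in every split at small n. Augmentation (training
only) samples uniform rotation in ±10°, per-axis translation in ±5 px
and per-axis scaling in [0.9, 1.1] per image per epoch, filling exposed
pixels with black to match the construct background. Three RNG streams
(initialization, shuffling, augmentation) derive from one seed, so
disabling augmentation reproduces the other streams exactly. No class
weighting is applied; imbalance is addressed by augmentation and MCC
thresholding.

The network output is the softmax probability of the *unacceptable*
class — the risk, in [0, 1]. Checkpoints are single `.npz` archives of
parameters plus metadata.

## Threshold selection and evaluation (`spiroqc.evalkit`)

MCC = (TN·TP − FN·FP) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with the value
defined as 0 when any marginal vanishes (the chance convention).
Candidate thresholds are 0, 1 and midpoints between consecutive distinct
scores; the rule predicts unacceptable when risk ≥ threshold (boundary
inclusive); MCC ties go to the smallest threshold. The threshold is
selected on the **validation** split, never the test split.

Evaluation reports AUC (trapezoidal ROC integration, via scikit-learn)
and the threshold metrics sensitivity, specificity, accuracy, precision
and F1, each with a 95% percentile-bootstrap CI over 2000 resamples of
(score, label) pairs; resamples that lose a class are skipped, and
zero-denominator point metrics are reported as NaN with a warning.
Display rounding is two decimals.

## Explanation (`spiroqc.explain`)

Grad-CAM over the last convolutional block (the standard choice for a
small feature hierarchy): the target-class logit's gradient with respect
to the block's activations is averaged per channel, the weighted
activation sum is rectified, bilinearly upsampled to 224 × 224 and
max-normalized to [0, 1]. The explained class defaults to the predicted
one. Overlays blend the grayscale construct with a perceptually ordered
colormap (inferno) at opacity 0.4; the heatmap itself is never modified
by visualization.

## Reference experiment and problem sizes

`spiroqc.experiments.cough_detection_experiment` is the package's
end-to-end check: 200 synthetic reports (~35/65 unacceptable/acceptable,
all unacceptable cases strong coughs — amplitude 0.9·PEF, width 0.12 s —
30% of pages carrying a red overlay), constructs built for each, the
classifier trained from scratch (45 epochs, learning rate 3e-3, reference
batch size/augmentation/patience), threshold selected on validation, and
the untouched ~20-image test split evaluated with 500 bootstrap
resamples. The run takes a few minutes on one CPU; these sizes were
chosen as the smallest at which the separation is comfortably
demonstrated. With seed 1 it reaches test AUC 1.0 and flags a cough case
with risk > 0.99.

## Known limitations

- The curve model and artifact shapes are stylized; no claim is made
  that a classifier trained on them transfers to clinical reports.
- Vector PDFs cannot be ingested (no bundled rasterizer), and image-only
  PDFs rely on a deliberately narrow reader.
- OCR is out of scope: demographics require a text line source or
  sidecar CSV.
- The classifier is small and trained from scratch; with a few hundred
  images it detects strong artifacts, but subtle real-world
  unacceptability would need more data or a pretrained backbone.
- Binary decision only; artifact-type classification is not attempted.
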