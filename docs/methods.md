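# Methods

This note records the model, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Problem setting

Each observation is one transverse B-mode view of one muscle, with a manual
segmentation labelling muscle (1) and subcutaneous fat (2) pixels.
A subject contributes up to 7 muscle groups × 2 sides × 3 views.
Diagnosis (N, PM, DM, IBM) is assigned per subject and inherited by every
muscle, so the three binary problems are defined purely by cohort filters:

| problem | included | positive |
|---|---|---|
| A | N, PM, DM, IBM | PM, DM, IBM |
| B | N, IBM | IBM |
| C | PM, DM, IBM | IBM |

The positive class is the package's convention (the disease, and for C the
treatment-refractory subtype); it is stored on `ProblemSpec` and
overridable.

## Feature extraction

**Echointensity.** Means and sample ($n-1$) standard deviations of the raw
8-bit pixel values per tissue, plus the muscle/fat mean ratio. The ratio
normalizes for gain: fat brightness is comparatively stable across
subjects, so muscle/fat > 1 flags abnormally bright muscle. A fat region
with zero mean makes the ratio undefined and is treated as an error rather
than a 0/0 sentinel.

**Nakagami parameters.** Pixel intensities are treated directly as
amplitude samples of a Nakagami distribution, fitted per tissue by the
moment ("inverse normalized variance") estimator
$\hat\omega = \overline{x^2}$, $\hat m = \hat\omega^2/\mathrm{Var}(x^2)$
(sample variance). The estimator is closed-form and deterministic, which
matters for bit-reproducible runs; its finite-sample error is covered by
recovery tests at $n = 10^3 \ldots 10^5$. $\hat m$ is clamped at the
distribution's support bound 0.5 with a logged warning — sub-Rayleigh
estimates do occur on quantized or clipped pixels. A constant region has
undefined shape and raises. Two caveats are inherent to the data model, not
the estimator: real B-mode pixels are log-compressed, so Nakagami-on-pixels
is an approximation; and the 8-bit display range clips the upper tail of
bright, heavy-tailed regions, biasing $\hat m$ upward (visible in
`examples/02_extract_features.py`).

**Haralick texture.** The region's pixels are quantized to $G = 32$ uniform
bins over the region's own [min, max] (making the statistics invariant to
adding a constant to all pixels); symmetric co-occurrence matrices are
accumulated at distance 1 for 0°/45°/90°/135°, counting only pairs with
both pixels inside the region; each matrix is normalized and the 13
classical statistics are averaged across directions. Natural logarithms
throughout; $0\log 0 = 0$. Sum variance is centred on the sum average (the
standard correction of the original definition). For a single-level
(constant) region: angular second moment 1, entropy and contrast 0,
correlation defined as 0. The 14th statistic (maximal correlation
coefficient) is excluded; the vector is the documented 22 elements. Which
region carries texture is configurable; the default is muscle, where the
disease signal lives. All GLCM settings sit in `GLCMConfig` and are
recorded with each run.

The 22-element ordering — echo (5), Nakagami muscle (2), Nakagami fat (2),
Haralick (13) — is this package's convention; fitting speckle on both
tissues is what makes the arithmetic come out at 22.

## Classification

A random forest: 500 trees, bootstrap resampling, $\sqrt{22} \approx 4$
features per split, unlimited depth, fixed seed. These are standard
defaults; no tuning is performed, and the acceptance properties are
required to hold at them. Prediction pools one class vote per tree, so the
reported score is exactly (votes for positive)/n_trees and the decision
threshold is the majority vote (0.5). No probability calibration, no
threshold tuning, no subtype (multi-class) mode.

## Cross-validation and metrics

Folds (N = 5) are assigned to **muscle entities** (subject, muscle group,
side): all 1–3 views of one physical muscle share a fold. Views of the same
muscle are nearly replicate images, so splitting them across folds would
leak test information into training. A stricter subject-level grouping flag
exists for sensitivity analyses (all muscles of a subject share a fold).
Two further choices are interpretations and are made explicit here:
entities are stratified by class when dealt to folds (preventing
single-class folds in small cohorts), and per-fold metrics are averaged
rather than pooling confusion counts — which means the mean LR+ is not the
LR+ of the mean sensitivity/specificity.

Before folding, records are put in a canonical order (subject, muscle,
side, view) so results are invariant to manifest row order (bootstrap
sampling is order-sensitive).

Metrics per fold: accuracy, sensitivity, specificity, PPV, NPV, Cohen's
kappa (marginal-product chance agreement), LR+ = sens/(1−spec),
LR− = (1−sens)/spec. Degenerate denominators yield sentinels rather than
crashes: LR+ = ∞ at specificity 1, NaN PPV/NPV when no positive/negative
prediction was made (logged). Across-fold summaries are mean and sample SD
over the finite fold values; a fold with infinite LR+ is excluded from that
metric's summary and logged.

## Synthetic studies

The generator emulates the statistical structure the feature model assumes,
not the appearance of real ultrasound. Each image is a fat band
(25% of height by default) over muscle; each pixel is an independent
Nakagami draw; optional Gaussian blur correlates the texture; values are
clipped to [0, 255] and rounded. The study layout mirrors the acquisition
protocol: 33/19/14/14 subjects (N/IBM/PM/DM), 7 muscles, bilateral, up to
3 views, 499-row images 476 columns wide (318 at the rectus femoris's 6 cm
depth).

Tissue means carry **per-muscle-entity jitter** (`entity_sd`, default
8–12 intensity units depending on preset): each physical muscle's mean is
shifted by a N(0, entity_sd) draw. Without it, region statistics estimated
from ~10⁴ pixels are nearly noiseless and any class difference is trivially
separable. The jitter is deliberately per entity rather than per subject:
under the default entity-grouped cross-validation, a per-subject shift
would let the classifier match test muscles to training muscles of the same
subject — re-creating, on purpose, the leakage that subject-level grouping
exists to prevent. That behaviour is demonstrable by switching the jitter
unit, but the shipped presets are designed to be leakage-clean under the
protocol's own grouping.

Presets (generator conventions, not clinical measurements):

- `separable`: normal muscle $m = 1.8$, mean 50; affected muscle $m = 0.8$,
  mean 110; shared fat $m = 1.2$, mean 120 — the chronic fatty-replacement
  direction, bright heterogeneous muscle.
- `overlapping`: both classes $m = 1.2$, means 75 vs 90 with entity SD 12 —
  the classes share the speckle shape on purpose, since a shape difference
  alone is nearly noiseless at region size and would defeat the point of an
  "overlapping" preset.
- `null`: identical parameters for all diagnoses (negative control).

The affected parameters are shared by PM, DM and IBM, so problem C on
synthetic data is itself a null comparison. Reproducibility: every record
has its own seed substream keyed on (study seed, subject, muscle, side,
view) and entity jitter on (study seed, entity, tissue) — datasets are
byte-identical across runs, partially regenerable, and changing one
diagnosis's parameters leaves all other subjects' pixels untouched.

What passing synthetic tests shows: the pipeline recovers known tissue
parameters, respects grouping, and finds discrimination exactly when the
generator provides it, with accuracy ordered by class separation. What it
does not show: performance on real muscle ultrasound — no point-spread
function, attenuation, bone shadow, fascia, log-compression, or
muscle-specific anatomy is simulated, and real class overlap is not
calibrated to any clinical dataset.

## Problem sizes in the checks

The end-to-end checks run at reduced scale chosen to exercise the full
protocol structure while keeping a single-CPU run short: discrimination
checks use 40 subjects (20 per class), 2 views, 256×256 images over 3
seeds; the separation-ordering check uses 20 subjects at 128×128 over 5
seeds; `scripts/acceptance.py` uses a 26-subject roster-proportioned study
(10/6/5/5) at 128×128. The null-preset chance band is a 95% binomial
interval computed on the number of muscle entities — the independent
sampling unit of the grouped design — not the (classifier-correlated)
image count.

## Known limitations

- Nakagami-on-pixels ignores log-compression; estimates on bright regions
  are clip-biased (documented above).
- Metrics are per image; no per-muscle or per-patient vote aggregation.
- Masks must align pixel-for-pixel with images; no registration.
- The DCNN comparison arm of the original study design is out of scope, as
  are ROC analysis and between-method significance testing.
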