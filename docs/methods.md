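# Methods

This note records the models, parameter choices and numerical conventions
behind `hsibrain`, and what the synthetic experiments do and do not show.

## Sensor model and pre-processing

A snapshot-mosaic sensor tiles its pixel grid with repeating 5×5 blocks of
spectral filters, so one exposure carries 25 bands at 1/5 of the sensor
resolution in each spatial axis. The demosaicking convention used here is
row-major within the block: band `b` of cube pixel `(r, c)` lives at
sensor position `(5r + b div 5, 5c + b mod 5)`. The convention is not
dictated by the physics and is recorded in cube metadata; demosaicking is
a pure rearrangement (a bijection — no interpolation), so any consistent
convention round-trips. For the camera's 2045×1085 active area this yields
a 409×217×25 cube (2045/5 = 409; a published description of the same
sensor also circulates with "419", which the arithmetic rules out).

Calibration is the standard flat-field `Ic = (I − D)/(W − D)` per band
against a white ceramic reference and a lens-capped dark frame.
Denominators below `eps = 1e−6` (white ≈ dark: no usable signal) are
clamped and counted in a logged warning rather than poisoning the cube
with infinities.

Sensor crosstalk — each band responding partly to its spectral neighbors —
is undone by right-multiplying each pixel's row-vector spectrum by a 25×25
spectral correction matrix (each row holds one virtual band's correction
coefficients). The synthetic crosstalk model must satisfy two constraints
at once: mixing rows sum to ≈1 (energy conservation) and the exported
correction matrix must be the exact inverse of the mixing in the
row-vector convention. Both hold simultaneously for a symmetric doubly
stochastic matrix, so the generator Sinkhorn-balances an exponential-decay
kernel (first-neighbor weight 0.08, decay length 1.2 bands, diagonally
dominant). With that choice the white and dark reference frames stay
spectrally flat and the noise-free forward model inverts to machine
precision (~1e−14 observed; the test bound is 1e−6).

RMS normalization divides each spectrum by `sqrt(Σ_b x_b²/B)`. Because the
brain surface is curved, pixels sit at different heights and collect
different light; any positive per-pixel scalar field applied to `I − D`
propagates multiplicatively through calibration and correction and cancels
exactly under this normalization (a tested identity). All-zero spectra
have no direction: they propagate as zeros and are flagged degenerate
rather than becoming NaN.

## Synthetic scenes

Signatures are smooth parametric curves over the 25 bands with a small
seeded smooth perturbation per class: healthy cortex rises gently into the
NIR; venous and arterial blood share a steep rise (arterial brighter and
shifted); dura mater is bright and nearly flat — the most distinct class.
The tumor signature is `healthy + separation · u` with `u` a smooth unit
max-abs shape orthogonalized against the healthy spectrum, so the
healthy–tumor spectral angle grows strictly with the separation parameter
and separation 0 makes the classes literally identical. Within-class
spectral jitter (sd 0.01 for healthy/tumor, 0.02 for blood, 0.025 for
dura) and i.i.d. sensor noise (default sd 0.01 reflectance units) are
added per pixel; `noise_sd = 0` requests an idealized scene with both
disabled so exactness tests have an exact target.

Class regions are thresholded smoothed Gaussian random fields (smoothing
`min(rows, cols)/8`), assigned in class-id order with exact pixel counts;
default abundances mirror the real cohort's imbalance (healthy 45 %,
tumor 24 %, venous 5 %, arterial 2 %, dura 24 % of labeled pixels, ~84 %
of the image labeled). The illumination field is a low-order polynomial
dome with `amplitude = max/min − 1` (default 0.6). Unlabeled background
pixels carry a strongly sloped ramp spectrum: a flat gray surround would
be angularly close to the nearly-flat dura signature and alias under
spectral-angle labeling.

Inter-patient variability is modeled by giving each scene of a cohort its
own smoothly shifted signature library (`inter_scene_sd`, max-abs shift
per class). Because the shifts are spectrally smooth they span a
low-dimensional subspace; a classifier trained on a few scenes therefore
generalizes across shifts more easily than across arbitrary perturbations.
This is a known simplification — real inter-patient variation includes
physiology the generator does not model — so passing synthetic benchmarks
demonstrates the machinery, not clinical performance.

Defaults were calibrated once so the inter-patient experiment reproduces
the qualitative difficulty ordering of the real study (tumor hard, dura
easy): separation 0.08 as the "realistic" default, 0.3 for well-separated
benchmark suites, inter-scene sd 0.04 for cohort studies.

## Labeling

The ground-truth tool's semantics: the reference spectrum is the single
seed pixel's spectrum, every image pixel is compared (no connectivity
constraint), pixels within the SAM threshold receive the class, and later
actions overwrite earlier labels (interactive-tool behavior; a keep-first
policy is also available). Every action is appended to a provenance log
whose replay reproduces the map exactly. Census percentages use decimal
round-half-up to two decimals; the published census table this mirrors is
itself not perfectly uniform in its rounding (both truncated and rounded
cells occur), so agreement is asserted to one unit in the last printed
digit. The published per-class column sums are also not fully consistent
with the prose that accompanies them (1252 vs 1256 arterial pixels); the
per-row counts are treated as authoritative.

## Classifiers

SVM: `SVC(kernel="linear", C=1)`. RF: 100 trees, seeded. Both consume
RMS-normalized 25-band spectra.

The 3D-CNN consumes 9×9×25 patches centered on the target pixel (mirror
padding of 4 pixels at borders so no labeled pixel is dropped). The
architecture is two conv blocks — 3D valid convolution (128 then 256
filters), batch norm, max pooling over the spectral axis only (kernel 2),
ReLU — then dense 256 → dropout 0.3 → dense 128 → dropout 0.5 → softmax
over 5 classes; shape trace 9×9×25 → 7×7×21 → 7×7×10 → 5×5×6 → 5×5×3 →
19200 flat. Kernel sizes (3×3×5) and dense widths are free choices
(config-overridable); the dropout values are read as rates 0.3/0.5.
Training: cross-entropy, AdamW (lr 5e−5, weight decay 0.01 on weight
matrices), 1024-patch mini-batches, two passes over the shuffled set.
Everything is NumPy: im2col + GEMM convolutions with hand-coded gradients,
verified against finite differences. Mini-batches are processed as
128-patch micro-batches with gradient accumulation to bound memory;
batch-norm statistics are per micro-batch, and running statistics are
seeded from the first batch (with so few optimizer steps, momentum alone
would leave them near their (0,1) initialization at evaluation time). The
classifier head is zero-initialized so the few-step regime does not fight
random initial class preferences.

### The two-pass budget at desk scale

The CNN's optimization budget is `2 · N / 1024` AdamW steps — it scales
with the training-set size. At the cohort scale the original design targets
(tens of thousands of labeled pixels) that is on the order of a hundred
steps; at the desk-scale sample counts used throughout this package
(hundreds to a couple thousand patches, chosen so the whole suite runs in
minutes on one core) it is only a handful. Adam's per-weight normalization
makes each step's magnitude ≈ lr = 5e−5, so a handful of steps cannot
order the softmax head's logits regardless of how separable the features
are: the trained-at-budget network scores near chance on phantoms that a
linear SVM on the same pixels classifies perfectly. The same architecture
reaches >0.93 held-out accuracy when the optimizer is given an adequate
budget (e.g. lr 1e−3, 10 passes — a tested property). The acceptance test
asserting 0.95 held-out accuracy *at the fixed two-pass budget* therefore
fails by design at desk scale and is left failing with this analysis
rather than weakened; it documents a real property of the training
schedule, not an implementation defect.

## Cross-validation and experiments

Stratified 5-fold assignment shuffles each class with the seeded generator
and deals samples round-robin, so per-class fold sizes differ by at most
one; a class with fewer than 5 samples is rejected by name. Double CV:
outer 5-fold isolation, inner re-stratified 5-fold on the remaining 80 %,
5×5 = 25 models trained, best-validation-OACC model per outer fold, best
test-OACC fold supplies the final model, used as-is without refitting.
Ties break toward the lowest fold index for determinism. All stage seeds
derive from the master seed by fixed mixing, and every model records the
fingerprint of its exact calibration subset, so fold isolation is
checkable after the fact.

Experiment A (intra-patient) adds the outer loop over the five per-image
fold groupings (the same grouping index for every image — 5 × 25 = 125
models) and reports per-image metrics both on the held-out 20 % folds and
on full-image predictions, since either reading of the original protocol
is defensible. Experiment B (inter-patient) is leave-one-image-out over
double CV (n × 25 models); the selected model never sees its test image.
Because 125 CNN trainings are out of reach of a desk-scale budget (one
training is already minutes of GEMM on a core), the CNN's
Experiment-A-style benchmark uses the Experiment-A outer split itself —
per-image stratified folds, one 80/20 grouping, a single training at the
full published hyperparameters.

## Metrics

All metrics derive from the 5×5 confusion matrix by one-vs-rest
decomposition; `ACC + Error = 1` is an identity and OACC equals the
count-weighted mean of per-class sensitivities (both tested). Metrics that
are undefined for a matrix (sensitivity of an absent class, blood
sensitivity with no blood samples) are reported as `None`, never 0, so
means are not silently deflated. Merged-blood sensitivity counts
venous↔arterial cross-predictions as hits by default (the clinical
distinction is secondary); a strict variant keeps them as errors.
Mean ± SD across images uses population SD (ddof 0), matching the summary
rows of the per-patient tables it mirrors; sample SD is switchable.
Band-efficiency = OACC(%) / band count, reported to two decimals with
round-half-up; one published comparator row (96.7 % over 826 bands) prints
0.11 where this rounding gives 0.12 — noted as an inconsistency in the
source table.

## Problem sizes

Test and analysis problem sizes are the package's own desk-scale choices:
phantom scenes of 32×32–64×64 pixels, cohorts of 2–4 scenes, 100–250
patches per class for CNN runs, triple CV with SVM/RF on ~1.3k labeled
pixels per scene. They keep the full suite in single-digit minutes on one
core while exercising every code path; none of the quantitative claims
about the real cohort depend on them (those are arithmetic over the
published tables).

## Known limitations

No radiative-transfer tissue optics, chromophore modeling, specular glare
or instruments in scenes; SAM thresholds used by the original annotators
are unknown, so labeling demonstrations choose thresholds from the known
signature geometry; only patch size 9 is implemented for the CNN (the
published sweep 3–21 is out of scope); no class weighting or significance
testing, mirroring the original protocol.
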