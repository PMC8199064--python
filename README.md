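# hsibrain

Intraoperative hyperspectral brain-tissue classification at desk scale:
snapshot-mosaic phantom simulation, reflectance pre-processing, spectral-
angle ground-truth labeling, three supervised pixel classifiers and the
nested cross-validation experiments that evaluate them.

## The problem

During glioma surgery the margin between tumor and healthy cortex is hard
to see. A snapshot-mosaic hyperspectral camera records 25 reflectance bands
(655–975 nm) in a single exposure by tiling the sensor with repeating 5×5
spectral filter blocks; a classifier then labels every pixel as healthy
tissue, tumor, venous blood, arterial blood or dura mater, producing a
classification map the neurosurgeon can read in real time.

The package implements the full chain for that setting:

1. **Synthetic scenes** (`hsibrain.synthetic`) — the real in-vivo captures
   are private, so a phantom generator produces raw mosaic frames with
   known per-pixel ground truth: smooth 25-band tissue signatures (healthy
   ≈ tumor with a tunable separation, venous ≈ arterial, dura most
   distinct), blobby class regions with realistic imbalance (arterial
   ~2 % of labeled pixels), a smooth illumination dome, sensor noise and a
   diagonally dominant band-crosstalk matrix.
2. **Pre-processing** (`hsibrain.preprocess`) — demosaic to a cube
   `I(r,c,b)`, calibrate `Ic = (I − D)/(W − D)` against white/dark
   references, un-mix crosstalk with the 25×25 spectral correction matrix
   (`Isc = Ic × SCM`), and normalize each pixel by its spectral RMS,
   `coef(r,c) = sqrt(Σ_b Isc² / B)`, so spectral shape survives brightness.
3. **Labeling** (`hsibrain.labeling`) — the spectral angle mapper
   `SAM(x, ref) = arccos(⟨x, ref⟩ / (‖x‖‖ref‖))` with a user threshold
   reproduces the interactive ground-truth tool, with a replayable
   provenance log.
4. **Classifiers** (`hsibrain.classify`, `hsibrain.cnn`) — linear SVM and
   100-tree random forest on per-pixel spectra (scikit-learn), and a
   patch-based 3D-CNN (9×9×25 patches, conv blocks of 128 and 256 filters
   with spectral-only max pooling, AdamW lr 5·10⁻⁵, weight decay 0.01,
   1024-patch batches, two passes) implemented self-contained in NumPy.
5. **Validation** (`hsibrain.validate`) — stratified 5-fold sampling,
   double 5-fold cross-validation (exactly 25 models per selection),
   Experiment A (intra-patient, triple CV over 80/20 fold groupings) and
   Experiment B (inter-patient, leave-one-image-out).
6. **Metrics** (`hsibrain.metrics`) — confusion matrix, OACC, per-class
   ACC/SEN/SPE/Error (one-vs-rest), merged-blood sensitivity, and the
   band-efficiency metric OACC/bands for comparing cameras with different
   spectral resolution.

## Worked example

```bash
python analysis/01_simulate_phantoms.py   # 4 phantom scenes + census
python analysis/02_preprocess_phantoms.py # chain + numerical checks
python analysis/03_sam_labeling.py        # SAM labeling vs true regions
python analysis/04_experiment_a.py        # intra-patient triple CV
python analysis/05_experiment_b.py        # inter-patient sweep
python analysis/06_band_efficiency.py     # OACC-per-band table
```

`02` prints the chain's guarantees on a noise-free rendering:

```
"max_rms_deviation": 3.33e-16,
"noise_free_roundtrip_max_abs_error": 1.09e-14
```

i.e. calibration plus spectral correction exactly invert the simulated
sensor, and every normalized pixel has unit RMS. `05` prints the
inter-patient difficulty trend (leave-one-scene-out, linear SVM):

```
separation 0.0:  tumor SEN 0.749  dura SEN 1.000  OACC 0.770
separation 0.01: tumor SEN 0.900  dura SEN 1.000  OACC 0.824
separation 0.02: tumor SEN 0.970  dura SEN 1.000  OACC 0.925
separation 0.05: tumor SEN 1.000  dura SEN 1.000  OACC 0.996
```

— as the healthy↔tumor spectral separation shrinks, tumor sensitivity
degrades while dura mater stays easy, the qualitative signature of the
inter-patient setting. `06` prints the band-efficiency comparison: the
best 25-band result contributes 2.4 % OACC per band versus 0.63 % for the
best published higher-band comparator, a 3.81× advantage ratio.

A `hsibrain` command-line tool exposes the same pipeline
(`generate`, `preprocess`, `label`, `train`, `predict`, `experiment`,
`report`); run `hsibrain --help`.

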