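# eegfusion

Dual-branch decoding of single-limb motor-imagery EEG. A raw-signal CNN
(temporal convolutions over a channels × samples epoch) and a VGG16-style
image CNN (Morlet scalograms of CSP "virtual channels", rendered as
64×64 RGB maps) are trained per cross-validation fold; their
penultimate-layer activations are concatenated and classified by a linear
SVM. The package ships a synthetic ERD-structured EEG generator so the
entire pipeline is testable offline, plus a classical CSP log-variance
baseline, stratified five-fold evaluation, chance-corrected kappa, and
paired t-test comparisons.

The neural-network layers (conv / max-pool / dense with Adam and explicit
backprop) are implemented on NumPy so the package runs on a bare
scientific-Python stack with no deep-learning framework.

## Pipeline stages

| module       | role |
|--------------|------|
| `synth`      | seeded ERD generator: band-limited class sources through a fixed orthonormal mixing matrix over 1/f noise; `band_power` oracle |
| `preprocess` | channel selection, 8–30 Hz zero-phase Butterworth band-pass, integer decimation to 250 Hz, 4 s windows (20×1000 epochs) |
| `csp`        | common spatial patterns (generalized eigendecomposition of trace-normalized class covariances), one-vs-rest extension, virtual-channel extraction (first/last m rows) |
| `tfmap`      | L2-normalized complex Morlet CWT, time-binned scalograms, jet-colormapped 64×64×3 images |
| `branches`   | the two CNN branches and deterministic Adam training; penultimate-feature extraction |
| `fusion`     | feature concatenation, per-dimension standardization, SVM |
| `evaluate`   | stratified 5-fold CV with strictly train-only fitting, accuracy / kappa / confusion matrices / paired t-tests, CSP baseline |
| `pipeline`   | YAML run configs, the `full` and `desk` (single-CPU) profiles, artifact output |

## CLI

```
eegfusion synth --n-classes 2 --n-trials-per-class 50 --erd-depth 0.8 \
    --seed 1 --out epochs.h5
eegfusion preprocess epochs.h5 --band 8 30 --fs 250 --window 0 4 --out prep.h5
eegfusion evaluate prep.h5 --pipeline fusion --profile desk --seed 1 --out runs/demo
eegfusion run --pipeline fusion --classes binary --seed 1 --out runs/full
eegfusion show-config > config.yaml
```

Pipelines: `fusion` (both branches + SVM), `eeg` (raw-signal branch alone),
`tf` (image branch alone), `csp` (log-variance baseline). Each output
directory contains the resolved config, seed, per-fold report JSON and a
CSV summary — enough to reproduce the run exactly.

## Data formats

Epoch containers are HDF5 files (`/data` trials×channels×samples,
`/labels`, attrs `fs`, `channel_names`, `class_names`) or a plain-text
directory (one whitespace matrix per trial + `labels.csv` + `meta.csv`).
CSP models serialize to HDF5 (`/W`, `/eigenvalues`).
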