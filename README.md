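# vcgmi

Single-lead derived vectorcardiography (VCG) and myocardial-infarction (MI)
beat classification, as a reusable, tested Python package.

The pipeline has four stages:

1. **Preprocessing** — resample every record to 500 Hz, then zero-phase
   band-pass filter 0.5–150 Hz (4th-order Butterworth, forward–backward).
2. **VCG synthesis** — a patient-specific, two-layer LSTM (30 units per
   layer, implemented in numpy with explicit backpropagation through time)
   maps a sliding window of lead-I samples to the synchronous Frank X/Y/Z
   amplitudes. A feedforward baseline with the same windowing contract and
   RMSE / uncentered-correlation fidelity metrics are included.
3. **Feature extraction** — Pan-Tompkins R-peak detection on a reference
   lead, beat segmentation between neighboring R peaks, period
   normalization to 400 samples via cubic splines (time factor `alpha`),
   min-max scaling (per-lead amplitude factor `beta`), and least-squares
   cubic B-spline fitting on a clamped knot-average knot vector. With
   n = 15 each lead yields 16 coefficients; three leads plus `alpha` and
   the three `beta` factors give the 52-dimensional per-heartbeat feature
   vector.
4. **Classification** — SMOTE oversampling (fitted inside training folds
   only), z-scoring, and a 52–300–275–12 multilayer perceptron (ReLU hidden
   layers, softmax output, cross-entropy loss), evaluated with stratified
   5-fold cross-validation and one-vs-rest ACC/SEN/SPE confusion-matrix
   metrics.

A seeded synthetic multi-lead ECG generator (`vcgmi.synthetic_ecg`)
produces records whose four leads (i, vx, vy, vz) are projections of a
shared Gaussian-kernel dipole trajectory, with class-conditional morphology
perturbations, baseline wander, and noise. It stands in for clinical data
in every test. Reference confusion matrices from a published single-lead
derived-VCG MI study are bundled as TSV fixtures (`vcgmi/data/`) and serve
as golden values for the metric definitions.

## Command line

The `vcgmi` entry point exposes the pipeline stages:

```sh
vcgmi simulate --class-label IMI --duration 60 --seed 1 --out rec.tsv
vcgmi preprocess --record rec.tsv --out prep.tsv
vcgmi train-synth --record prep.tsv --window 150 --epochs 300 --model synth.npz
vcgmi derive --model synth.npz --record prep.tsv --out derived.tsv
vcgmi beats --record prep.tsv --reference-lead vx --out beats.tsv
vcgmi features --record prep.tsv --label IMI --out features.tsv
vcgmi train-clf --features features.tsv --folds 5 --seed 1 --out clf_out/
vcgmi evaluate --confusion clf_out/confusion.tsv
vcgmi run-all --config config.yaml --out run_out/
```

`run-all` drives the whole pipeline from a declarative YAML file (any
`PipelineConfig` field, e.g. `classes`, `beats_per_class`, `vcg_source:
measured|derived`, `lead_config: xyz|x|y|z|…`) and writes signal, beat and
feature tables, the pooled confusion matrix, a metrics report, and a
manifest with config hash and seeds for bit-identical re-runs.

## Layout

```
src/vcgmi/
  synthetic_ecg.py    seeded multi-lead generator + class perturbations
  signal_io.py        MultiLeadRecord, WFDB(16) and delimited-text I/O
  preprocessing.py    resampling and zero-phase band-pass
  vcg_synthesis.py    windowing, LSTM (BPTT), MLP baseline, RMSE/CC
  beat_processing.py  Pan-Tompkins, segmentation, normalization
  spline_features.py  knot construction, Cox–de Boor basis, LS fitting
  classification.py   SMOTE and the softmax MLP classifier
  evaluation.py       confusion matrices, ACC/SEN/SPE, golden tables
  pipeline.py         end-to-end orchestration + cross-validation
  cli.py              click command group
tests/                pytest suite (tests/test_acceptance.py = criteria)
scripts/acceptance.py acceptance-target report
```
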