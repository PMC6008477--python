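# mcgkit

Feature extraction and classification for 6-axis chest-mounted inertial
recordings (seismocardiography + gyrocardiography), aimed at screening
cardiac conditions — normal sinus rhythm, atrial fibrillation, coronary
artery disease and STEMI — from smartphone accelerometer/gyroscope data.
Because clinical recordings of this kind are restricted, the package ships a
synthetic signal simulator that generates labelled cohorts with the
statistical structure the pipeline is sensitive to, so every stage is fully
testable offline.

## Pipeline

1. **Conditioning** — brick-wall FFT band-pass (1–40 Hz), then subtraction of
   a 50-sample moving average to suppress breathing (`mcgkit.preprocess`).
2. **Segmentation** — non-overlapping 10 s episodes; each episode split into
   eight 2.5 s sub-segments overlapping by 1.5 s.
3. **Rhythm features** (`mcgkit.rhythm`) — per axis: heart rate from
   short-term autocorrelation of the sub-segments (`mcgkit.heartrate`),
   three median-based HRV indices, approximate entropy, spectral entropy
   (1–11 Hz, 1/6-max noise floor), 11 turning-point ratios through a filter
   bank, and the turning-point ratio of the interval series — 18 values.
4. **Morphology features** (`mcgkit.morphology`) — 11 sub-band energies and
   four 59-bin 1-D uniform local-binary-pattern histograms (spacings 3 and
   21, raw and integrated signal) — 11 + 236 values.
5. **Assembly** (`mcgkit.assembly`) — 265 features per axis × 6 axes = 1590
   per 10 s segment (four-class mode; 254 × 6 = 1524 in three-class mode,
   which drops the energy block).
6. **Evaluation** (`mcgkit.classify`) — leave-one-person-out cross-validation
   with an RBF-kernel SVM (inner grid search over C) or a random forest,
   per-recording majority voting, confusion matrices, accuracy,
   sensitivity/specificity and per-class F1.

## CLI

```sh
# simulate a labelled recording (CSV + JSON ground-truth sidecar)
mcgkit simulate --condition afib --duration 60 --seed 7 --out afib.csv

# extract the per-segment feature table from a manifest (path,subject_id,label)
mcgkit extract --manifest manifest.csv --out features.csv

# leave-one-person-out evaluation with majority voting
mcgkit train-eval --features features.csv --classifier ksvm --seed 0 --out metrics.json

# human-readable summary
mcgkit report --metrics metrics.json
```

All pipeline constants (bands, window lengths, filter banks, classifier
hyper-parameters) live in `mcgkit.config.PipelineConfig` and can be supplied
as YAML via `--config`.

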