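# usvpipe

Detection, denoising and classification of mouse ultrasonic vocalizations
(USVs). The pipeline covers:

- **`usvpipe.synth`** — seeded generator of synthetic ultrasonic recordings
  (13 syllable classes plus broadband false positives) with ground-truth
  annotations and a rule-based oracle labeler built on frequency-trajectory
  rules (>5 kHz rise/fall, direction changes, component breaks, duration
  thresholds, harmonics).
- **`usvpipe.segment`** — an amplitude-threshold detector: exponential-mean
  background subtraction, cepstral spectral-envelope flattening, per-frame
  three-peak extraction (m1–m3 / f1–f3) and hysteresis segmentation into
  elements carrying frequency tracks.
- **`usvpipe.frontend`** — the Gammatone-spectrogram frontend: STFT
  (NFFT 750, 0.8-overlap Hamming, 251 bins over 20–120 kHz at 300 kHz),
  a 64-channel Gammatone filterbank with channel density concentrated at
  68 kHz, noise floor 10⁻³, log, order-1 ARMA smoothing, 3×3 median filter
  and a fixed 64×401 canvas.
- **`usvpipe.model`** — a CNN classifier implemented from scratch on numpy
  (im2col convolutions, batch norm, ELU, max pooling, dropout, He init,
  SGD with Nesterov momentum and L2), class-weighted cross-entropy
  (`cw_i = N/(c·n_i)`), 10% shift augmentation and snapshot-ensemble
  training on a cosine-annealing schedule (5 snapshots at the learning-rate
  minima of 40-epoch cycles).
- **`usvpipe.ensemble`** — bootstrap bagging (default B = 10),
  under-sampling to 124/class, SMOTE+ENN over-sampling, snapshot combiners
  (`sn`, `sn_avg_3`, `sn_xgb3`, `sn_xgb5` with a gradient-boosted stacker)
  and the bagged predictor that averages last-snapshot probabilities across
  members, plus mode-of-8-folds inference.
- **`usvpipe.evaluation`** — confusion matrices with row-normalized recall,
  class-wise/macro F1 with bootstrap SDs, class-pooling schemes
  (12/11/6/5/3/2 and the 6-class evaluation variant), detection TPR/FDR
  with greedy interval matching, inter-observer reliability and
  Manhattan-distance exemplar selection.
- **`usvpipe.cli` / `usvpipe.io_utils`** — WAV/CSV/NPZ formats, model
  bundles with config hashes, and the `usvpipe` command-line tool.

## CLI

```bash
# generate a synthetic recording + ground truth
usvpipe synth --n-usvs 200 --seed 1 --out-wav rec.wav --out-csv truth.csv

# detect elements, extract Gammatone spectrograms
usvpipe detect --wav rec.wav --out-csv detections.csv
usvpipe features --wav rec.wav --detections truth.csv --out feats.npz

# train a (reduced) bagged snapshot ensemble and predict
usvpipe train --features feats.npz --out-dir bag/ -b 3 --cycles 2 --cycle-len 10 --small
usvpipe predict --features feats.npz --model-dir bag/ --out-csv preds.csv --pool 6

# evaluate and inter-observer reliability
usvpipe evaluate --predictions preds.csv --truth truth.csv --out-json report.json
usvpipe ior --table-a obs1.csv --table-b obs2.csv --pool 2 --out-json ior.json
```

## Conventions

Times are seconds (6 decimal places in CSVs), intervals half-open
`[start_s, end_s)`, labels lowercase class abbreviations
(`c c2 c3 c4 c5 h d up u f us s ui` plus `FP` and `uc`). Default sample
rate is 300 kHz; other rates are resampled on read.
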