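# emgfusion

Dual-stream convolutional/recurrent feature-fusion classifier for surface
electromyography (sEMG) hand-gesture recognition, with a synthetic-data
generator so the full pipeline is testable without any external download.

The pipeline: multi-channel sEMG recordings (10 channels at 100 Hz in the
reference configuration) are high-pass filtered, Z-scored, cut into
fixed-length trials (500 samples for a 5-s gesture), and segmented into
sliding windows (200 ms / 20 samples, non-overlapping, 25 per trial). Five
time-domain features — MAV, ZC, SSC, WL, RMS — are computed per window per
channel, giving a 25 x 5 x 10 feature tensor alongside the 25 x 20 x 10 raw
windows. The model runs two per-window encoders (a conv stack on the
features; a conv stack with an inner LSTM on the raw samples), concatenates
their flattened outputs into a width-1792 fused vector, and feeds the
window sequence through two bidirectional LSTM layers and a dense head with
a per-window softmax over 52 gesture classes. Trial predictions are the
argmax of the window-mean probabilities.

No deep-learning framework is assumed: the network, backprop and Adam are
implemented on NumPy in `emgfusion.nn`, verified by numerical gradient
checks and an equation-level LSTM single-step oracle.

## CLI

```bash
emgfusion synth --classes 5 --reps 10 --subjects 2 --seed 1 --out raw/
emgfusion preprocess --recording raw/subject_00.h5 --out trials.h5
emgfusion featurize --trials trials.h5 --window-ms 200 --out features.h5
emgfusion train --features features.h5 --classes 5 --epochs 10 --out history.json
emgfusion evaluate --features features.h5 --classes 5 --out report.json
emgfusion trace-shapes --preset db1-dual   # diff realized shapes vs reference
```

Real acquisition files (MAT with `emg`, `stimulus`/`restimulus`,
`repetition` variables) load via `emgfusion.io.load_ninapro_mat`; the
`database="db2"` flag switches to the 12-channel / 2000 Hz layout.

## Scale notes

Training the full 52-class model on the real benchmark requires the
external dataset download and multi-hour training; that configuration is
preserved verbatim (`emgfusion.model.db1_spec()`,
`emgfusion.training.paper_scale_config()`). Tests and examples use
`desk_spec()` / `desk_scale_config()`, which shrink widths and epochs so
everything finishes in minutes on one CPU.
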