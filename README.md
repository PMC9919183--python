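# mfbeat

A tiny matched-filter-based CNN for inter-patient ECG heartbeat classification,
with everything around it: synthetic ECG generation, WFDB/fixture record I/O,
beat segmentation with AAMI label mapping, causal normalized RR-interval
features, matched-filter template extraction, the fused correlator-bank
network (pure NumPy, manual backprop), evaluation metrics, and a
noise-robustness sweep.

## How it works

1. **Records** — annotated single-lead ECG (WFDB records or a plain-text
   fixture dialect) are resampled to 128 Hz and cut into 64-sample windows
   centered on each annotated R-peak, labeled with the AAMI super-class of
   the beat symbol.
2. **RR features** — each beat's pre- and post-RR intervals are normalized by
   strictly causal trailing means of the last 80 (local) and 400 (global)
   intervals, giving four dimensionless ratios.
3. **Templates** — per sub-class (or super-class, or record × sub-class)
   means of the training windows (or of their first derivatives), optionally
   cropped to the central 32 samples, form a matched-filter bank.
4. **Model** — one wide Conv1D layer (kernels = the templates, optionally
   frozen) → batch norm → tanh → global max over time, concatenated with a
   32-16-8 dense embedding of the RR ratios, into a softmax head of 3/4/5
   classes. The whole thing is 1.3k–1.9k parameters.
5. **Training** — class-(optionally-)weighted categorical cross-entropy,
   Adam at 1e-3 with reduce-on-plateau, batch 512, up to 500 epochs with
   early stopping.

The conv branch is a matched-filter receiver made differentiable: with frozen
template kernels its output equals `correlate(window, template) + bias`
channel-wise, and the test suite asserts exactly that.

## CLI

```sh
mfbeat simulate --duration 300 --seed 1 --out data/rec0     # synthetic record
mfbeat convert path/to/mitdb/100 --lead MLII --out data/100 # WFDB -> fixture
mfbeat segment data/rec0 --out data/segments.csv
mfbeat extract-templates --segments data/segments.csv --feature derivative \
    --nk 32 --out data/bank.json
mfbeat param-count --classes 3 --nk 32 --frozen
mfbeat train --train-segments train.csv --val-segments val.csv \
    --bank data/bank.json --out runs/model
mfbeat evaluate --model-dir runs/model --segments test.csv --out runs/report
mfbeat noise-sweep --train-segments train.csv --val-segments val.csv \
    --test-segments test.csv --bank data/bank.json --mode test_only \
    --grid 0,10,20,30,40,50 --out runs/sweep.csv
mfbeat run --config config.yaml --seed 1                    # full pipeline
```

Exit codes: 0 success, 1 user error, 2 internal error.

## Layout

| Module | Role |
| --- | --- |
| `mfbeat.synthetic_ecg` | seeded sum-of-Gaussians beat generator with class RR dynamics and AWGN |
| `mfbeat.record_io` | `BeatRecord` type, plain-text fixture dialect, WFDB lead + beat-annotation reading |
| `mfbeat.wfdb_io` | minimal WFDB header/212/annotation parser (and a test-support writer) |
| `mfbeat.beat_dataset` | resampling, windowing, AAMI mapping, DS1/DS2 inter-patient split |
| `mfbeat.rr_features` | causal local/global dynamic-normalized RR ratios |
| `mfbeat.matched_filters` | template extraction, correlator, classical MF receiver |
| `mfbeat.mf_cnn` | model spec, closed-form parameter accounting, build + train |
| `mfbeat._nn` | NumPy layers/optimizer with manual backprop |
| `mfbeat.evaluation` | confusion-matrix metrics and the noise sweep |
| `mfbeat.app` / `mfbeat.cli` | run configs, manifests, `mfbeat` CLI |
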