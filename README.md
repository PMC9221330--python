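# physiofuse

Multi-modal wearable biosignal fusion for recognizing flight maneuvers
(takeoff, level flight, turn-and-hover, roll, somersault, stall) from five
physiological channels: ECG (512 Hz), GSR (64 Hz), EMG (1024 Hz), RESP
(64 Hz) and SKT (32 Hz).

The pipeline:

1. **simulate** — a synthetic cohort generator producing labeled
   multi-channel recordings with difficulty-dependent physiological trends
   (the original study's recordings are private), fully reproducible from a
   seed;
2. **preprocess** — per-subject z-score normalization, 20 %-rule
   ectopic/missing detection, 30-s tile rejection (> 20 % flagged),
   centered-11-point mean imputation, a per-channel Nyquist-guarded filter
   bank (wavelet/Gaussian/sliding-average denoise, high-pass, 50 Hz notch,
   low-pass), QRS detection, and downsampling to a common 2 Hz clock;
3. **features** — sliding-window (30 s window / 10 s step) extraction of 28
   fused features (table below);
4. **screen** — Pearson inter-feature correlation, Kendall tau-b
   feature-difficulty association, and feature selection (the published
   19-feature set, or an |r|-threshold mode);
5. **train / evaluate** — a confidence-weighted voting ensemble of four
   tree classifiers (ETC, DTC, GBC, XGBC), evaluated with stratified
   10-fold CV and leave-one-subject-out CV (precision/recall/F1, accuracy,
   label-code MSE, confusion matrices).

## CLI

```sh
physiofuse simulate --subjects 14 --seed 0 --out data/
physiofuse features --in data/ --out features.tsv
physiofuse screen   --features features.tsv --out screen.json
physiofuse train    --features features.tsv --select paper --out model/
physiofuse predict  --model model/ --features features.tsv --out preds.tsv
physiofuse evaluate --features features.tsv --scheme kfold10 --out eval.json
physiofuse demo     --seed 0 --out demo/          # full synthetic study
```

`demo` simulates 14 subjects, runs every stage, and writes per-classifier
and ensemble reports plus a `summary.json` (completes on one CPU well
inside 15 minutes at default scale).

## The 28 features (canonical order)

| block | features | notes |
|---|---|---|
| ECG (13) | `ecg_value`, `hr`, `nn`, `sdnn`, `sdsd`, `rmssd`, `pnn50`, `pnn20`, `ulf`, `vlf`, `lf`, `hf`, `lf_hf` | HRV time stats from gated (300–2000 ms) RR intervals; band powers from a 4 Hz tachogram over a rolling ≤ 5-min buffer truncated at the behavior-segment start; pNN thresholds are strict `>` |
| GSR (3) | `sc_value`, `sc_mean`, `sc_std` | window statistics of the cleaned skin-conductance signal |
| EMG (7) | `emg_value`, `emg_mean`, `emg_std`, `emg_rms`, `iemg`, `emg_mf`, `emg_mpf` | `emg_mean`/`emg_std` are computed on the **rectified** signal (the raw mean of a high-passed EMG is identically ~0; the rectified mean is proportional to iEMG, matching their reported high correlation); MF splits the Welch PSD area in half, MPF is the PSD-weighted mean frequency |
| RESP (4) | `resp_value`, `resp_mean`, `resp_std`, `resp_freq` | dominant spectral peak in 0.05–1 Hz with parabolic refinement |
| SKT (1) | `skt_value` | 2 Hz downsampled skin temperature at window end |

`*_value` features are the 2 Hz downsampled stream sampled at the window
end. Windows with < 2 min of in-segment beat history get missing
`ulf`/`vlf` and are flagged (not silently dropped); training and
evaluation drop flagged rows with a logged count.

The 19-feature selected set (`--select paper`): `nn`, `sdnn`, `pnn50`,
`pnn20`, `vlf`, `lf`, `hf`, `resp_value`, `resp_mean`, `resp_std`,
`sc_value`, `sc_mean`, `sc_std`, `emg_mean`, `emg_std`, `emg_rms`, `iemg`,
`emg_mf`, `emg_mpf`.

## File formats

All artifacts are plain text:

* channel CSV: `# subject=<id> kind=ECG rate=512 start=0` header, then
  `time_s,value` rows;
* labels CSV: `start_s,end_s,label` with half-open `[start, end)` segments;
* feature TSV: `subject  window_start_s  <28 features>  label`;
* difficulty CSV: one row per subject, one column per behavior (integer
  ratings 1–10); the packaged table ships in `physiofuse/data/`.

## Notes on fidelity

* The ectopic rule's reference is the previous *accepted* sample; after 8
  consecutive flags the current level is accepted as the new reference so a
  genuine level shift does not cascade (`max_run=None` restores the
  literal frozen-reference rule).
* The relative-change rule is applied where a percent change is physically
  meaningful: raw GSR/SKT samples and the derived RR series. Zero-mean
  oscillatory channels (ECG/EMG/RESP) get non-finite flagging plus the
  physiologic RR gate.
* The SKT filter-table row (5 Hz high-pass / 200 Hz low-pass at 32 Hz) is
  skipped and logged; a 5 Hz high-pass would erase a skin-temperature
  signal, and 200 Hz exceeds Nyquist.
* Label-code MSE depends on the (documented, configurable) 0–5 behavior
  codebook and is order-sensitive by construction.
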