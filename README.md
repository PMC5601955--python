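# emgpr

A myoelectric pattern-recognition pipeline for multichannel surface EMG
(sEMG), built around a lower-limb recording protocol: synthetic session
generation standing in for the acquisition hardware, signal treatment,
time-domain feature extraction, pairwise linear discriminant analysis with
one-vs-one voting, a simulated real-time motion test with its four
performance metrics, nonparametric configuration-comparison statistics,
and pain-outcome scoring for longitudinal follow-up.

## What it does

- **`emgpr.sessions`** — session data model (protocol, contraction ranges,
  signal in post-gain volts) and an on-disk bundle format (`session.json`
  plus `signal.f32` or `signal.csv`), with channel-subset selection.
- **`emgpr.synth`** — synthetic sessions: movement-specific spatial
  activation across channels, band-limited (20–450 Hz) Gaussian carrier
  under a trapezoidal effort envelope at 70% effort, baseline noise, and a
  modeled amplifier front end (1st-order 1 Hz high-pass, 3rd-order
  Butterworth 750 Hz low-pass, gain 200, 16-bit mid-tread quantization).
  An `overlap` knob interpolates the activation patterns toward zero, so
  downstream accuracy degrades to chance at `overlap=1`.
- **`emgpr.preprocess`** — 15% bilateral contraction trimming (4 s → 2.8 s),
  per-movement concatenation (3 × 2.8 s → 8.4 s), and sliding-window
  segmentation (200 ms windows, 50 ms increment). Two window-count
  conventions: `closed_form` (165 windows on the default signal) and the
  default `paper163` (163), which drops the two end-aligned windows.
- **`emgpr.features`** — per-window, per-channel MAV, waveform length,
  slope sign changes, and zero crossings (optional deadband), and a
  stratified 40/20/40 training/validation/test split with
  largest-remainder rounding.
- **`emgpr.lda`** — ridge-stabilized pairwise LDA (equal priors, midpoint
  bias) with majority voting; deterministic margin-sum/lowest-index
  tie-breaks; JSON model serialization.
- **`emgpr.motiontest`** — streaming motion-test simulation: prompts in
  random order, first prediction at 211 ms (200 ms window + 11 ms
  processing), one prediction every 50 ms, 20 correct predictions required
  before a 10 s timeout. Metrics: selection time (floor 0.211 s),
  completion time (floor 1.161 s ≈ 1.16 s), completion percentage,
  real-time accuracy (e.g. 20 correct in 25 predictions → 80%), plus the
  cumulative completion curve.
- **`emgpr.stats`** — mean/SE summaries, exact Wilcoxon signed-rank and
  rank-sum tests by permutation enumeration (normal approximation with tie
  correction for large samples), and Bonferroni adjustment. Complete
  separation of two size-6 samples attains p = 2/C(12,6) ≈ 0.002.
- **`emgpr.pain`** — questionnaire scoring: NRS, pain rating index (sum of
  descriptor scores), weighted pain distribution (Σ k·p_k over pain levels
  0–5), sleep hours, and first-vs-last / follow-up change summaries.
- **`emgpr.config` / `emgpr.pipeline` / `emgpr.cli`** — YAML/JSON config
  with validation, seed derivation, and the all-in-one experiment driver
  (per-subject sessions → training → motion tests → condition comparison).

## CLI

```sh
emgpr validate  --config config.yaml
emgpr synth     --config config.yaml --seed 1 --out session_dir/
emgpr train     --config config.yaml --session session_dir/ --out model.json
emgpr motiontest --config config.yaml --model model.json --out mt_out/
emgpr compare   --table-a a.csv --table-b b.csv --independent --out cmp.csv
emgpr pain-report --in pain.csv --out report.json
emgpr run       --config config.yaml --seed 1 --out experiment_out/
```

All config sections are optional; defaults reproduce the standard protocol
constants (2 kHz, 16 channels, 8 movements, 3 × 4 s contractions with 4 s
rest, 15% trim, 200/50 ms windows, 40/20/40 split, 20 correct / 10 s
motion test, Bonferroni family of 5 metrics).

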