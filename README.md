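# uemg

Simulation and analysis of slow-wave uterine electromyography (EMG).

The package builds a complete, testable replica of an intrauterine-EMG
analysis pipeline for comparing uterine electrical activity between the
proliferative (PP) and luteal (LP) phases of the menstrual cycle:

- **`uemg.synth`** — a physiologically motivated synthetic recording
  generator: a quasi-periodic contraction slow wave (0.8–6 contractions/min)
  on electrode 1, with gated spike bursts, baseline drift, 50 Hz mains,
  cardiac and respiration tones, and white noise. PP presets are faster and
  lower-amplitude; LP presets slower and higher-amplitude. Fully seeded and
  reproducible.
- **`uemg.preprocess`** — 5-minute segmentation (max 2 segments per
  recording), mean subtraction, eighth-order 0.1 Hz Butterworth lowpass
  (cascaded second-order sections; causal single-pass by default, zero-phase
  optional), ×8 decimation from 256 Hz to 32 Hz.
- **`uemg.features`** — per-segment features: RMS, peak and peak-to-peak
  voltage from the time samples; peak, power-weighted-mean and median
  frequency from a single unwindowed periodogram, band-limited to
  (0, 0.1 Hz] by default.
- **`uemg.stats`** — two-sided Wilcoxon rank-sum comparison of PP vs LP
  feature distributions (exact for small tie-free samples, tie-corrected
  normal approximation otherwise), summarized as median (IQR).
- **`uemg.study`** — end-to-end orchestration (cohort → segments → features
  → comparison), analytic design numbers (frequency resolution, contraction
  detection limit), provenance-tagged outputs.
- **`uemg.io`** — recordings as CSV + YAML sidecar or EDF (minimal
  self-contained EDF reader/writer, 16-bit quantization).

## CLI

```sh
uemg design                                   # analytic design numbers
uemg simulate --phase both --n-pp 11 --n-lp 15 --seed 1 --out recs/
uemg preprocess --in recs/PP-000.csv --channel 1 --out segments.csv
uemg features --in segments.csv --out features.csv
uemg compare --features features.csv --alpha 0.05 --out cmp/
uemg run-study --config study.default.yaml --seed 1 --out study_out/
```

`study.default.yaml` holds the default simulated-study configuration
(11 PP / 15 LP recordings of 10 minutes each). `run-study` writes the
feature table, the six-feature comparison table, a design report and
PP-vs-LP boxplots, all tagged with the master seed and a config hash.

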