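# eegsel

Optimal small bilaterally-symmetric EEG montage search for two-group
(MCI vs HC) classification.

The package implements an end-to-end pipeline for finding the best
2/4/6/8-electrode configuration of a 32-channel resting-state EEG montage:

- **preprocessing** — per-channel baseline correction, zero-phase Butterworth
  band-pass (0.5–50 Hz), 5-s epoch segmentation, 75 µV amplitude-based
  artifact rejection and seeded random subsampling to a fixed epoch count
  (`eegsel.preprocessing`, minimal EDF I/O in `eegsel.io`);
- **features** — per channel: absolute/relative band power in nine sub-bands
  (δ, θ, α_L, α_H, α, β_L, β_H, β, γ), 14 phase–amplitude couplings
  (envelope-to-raw coherence), Hjorth activity/mobility/complexity, Shannon
  entropy, largest Lyapunov exponent (nearest-neighbor divergence), Hurst
  exponent (rescaled range) and normalized Lempel–Ziv (LZ76) complexity;
  per symmetric pair: differential and rational band-power asymmetry.
  Full montage: 39×32 + 18×14 = **1500** epoch-averaged features per subject
  (`eegsel.spectral`, `eegsel.nonlinear`, `eegsel.features`);
- **configuration search** — exhaustive enumeration of all electrode sets
  built from whole symmetric pairs plus midline electrodes
  (20/176/924/3276 configurations for sizes 2/4/6/8) and ranking by
  cross-validated accuracy (`eegsel.config_search`);
- **evaluation** — leave-pair-out cross-validation (one subject per class
  held out per fold; 21×21 = 441 folds at full scale) with per-fold
  z-scoring, Fisher-score feature ranking, an N = 1..15 feature sweep and a
  linear SVM (`eegsel.evaluation`);
- **statistics** — chi-square, pooled two-tailed t-test (raw or summary
  input), one-sample KS normality gate and Bonferroni-corrected Wilcoxon
  signed-rank comparisons with star annotations (`eegsel.group_stats`);
- **synthetic cohorts** — fractional-Gaussian-noise EEG backgrounds with
  group-dependent Hurst exponents, planted inter-hemispheric delta
  asymmetry and group-dependent theta→high-beta phase–amplitude coupling,
  so the whole pipeline is testable without clinical data
  (`eegsel.synthetic`).

## CLI

```bash
# synthetic cohort -> feature table -> configuration ranking -> device comparison
eegsel simulate --spec cohort.yaml --out cohort/
eegsel extract  --cohort cohort/ --out features.csv
eegsel search   --k 2,4 --features features.csv --out ranking.csv
eegsel compare  --features features.csv --ranking ranking.csv --out report.csv

# or everything at once, with a reproducibility manifest and stage caching
eegsel run --config pipeline.yaml --out results/

# preprocess continuous EDF recordings instead of simulating
eegsel preprocess --edf S01.edf --group MCI --out cohort/
```

`pipeline.yaml` example:

```yaml
cohort: {n_per_group: 21, fs: 250.0, epochs_per_subject: 20, rng_seed: 1}
search: {k: [2, 4]}
evaluation: {max_features: 15, kernel: linear}
compare: {family_size: 20}
```

The full k = 8 search (3276 configurations × 441 folds) is an
overnight-on-one-CPU job; k = 2 at reduced scale runs in minutes.

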