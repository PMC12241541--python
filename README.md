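# wm-dynamics

Analysis pipeline for trial-locked BOLD dynamics on parcellated fMRI time
series, exercised end-to-end on a built-in synthetic data generator that
emulates a two-day, eight-scans-per-day working-memory-manipulation design
(35 s blocks: 5 s instruction + 9 three-second trials, 3 per difficulty
level, TR = 1 s, 482-region parcellation).

Stages:

- **`synthetic_data`** — seeded trial schedules, trial-level behaviour
  (linear-probability accuracy, linear RT), and parcellated BOLD with
  difficulty-scaled HRF-shaped responses; a configurable region subset
  responds 3 s late on incorrect trials.
- **`fir_model`** — canonical double-gamma HRF, data-driven FIR window
  (first negative sample of the boxcar convolution: 14 s → 15 frames),
  indicator FIR designs with day/scan nuisance (the Hard–Incorrect model
  has 15 + 1 + 16 = 32 regressors), per-participant least-squares fits.
- **`latent_axes`** — per-slice z-scoring, PCA over (participant ×
  condition × timepoint) observations, LDA sweeps across timepoints ×
  PC counts under subject-grouped 5-fold CV with balanced accuracy,
  Gram–Schmidt orthonormalisation of the two discriminant axes, region
  and trajectory projections.
- **`region_selection`** — quadrant assignment in the two-axis plane,
  signed-area net-BOLD statistic, per-region mixed models of the
  difficulty effect with Benjamini–Hochberg FDR.
- **`temporal_dynamics`** — per-lag-normalised cross-correlation and
  delay detection; Gaussian-KDE probability/energy landscape
  (`E = −ln P`) of |BOLD| amplitude per timepoint.
- **`behavior_stats`** — trial-level mixed models of accuracy and RT on
  difficulty and day.

## CLI

```sh
wm-dynamics simulate --config config.yaml --out data/ --seed 1
wm-dynamics behavior --events data/events --out out/behavior
wm-dynamics fir --events data/events --bold data/bold --window auto --out out/fir
wm-dynamics lda --betas out/fir/betas.tsv --contrast easy-hard --out out/lda --seed 1
wm-dynamics regions --betas out/fir/betas.tsv --out out/regions --seed 1
wm-dynamics delays --betas out/fir/betas.tsv --pair hard-correct:hard-incorrect --out out/delays
wm-dynamics landscape --betas out/fir/betas.tsv --condition hard-correct --out out/landscape
```

`config.yaml` holds `GeneratorParams` overrides (e.g. `n_participants: 8`,
`noise_sd: 0.5`). All outputs are plain TSV/JSON.

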