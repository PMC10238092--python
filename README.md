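# owlspace

Analysis pipeline for binaural spatial-cue statistics and midbrain
spatial-tuning in owl-like heads:

- **`hrtf_io`** — read/write binaural head-related impulse-response (HRIR)
  sets in a JSON-manifest + stereo-WAV dialect, with an optional read-only
  SOFA (`SimpleFreeFieldHRIR`) loader and grid validation.
- **`synthetic_data`** — a parametric "owl head" generator (linear
  ITD-azimuth law, facial-ruff frontal high-frequency gain lobe, elevational
  and azimuthal ILD components, ruff-removed variant) and a Poisson
  spike-count tuning-curve simulator with known ground truth.
- **`ipd_reliability`** — interaural-phase-difference (IPD) reliability
  under concurrent-sound corruption: target+masker rendering, gammatone
  filterbank (1–8 kHz, 200 Hz steps), per-band IPD from the maximum
  cross-correlation lag, circular SD across masker locations, inverse-SD
  reliability, per-location normalization, cross-owl averaging, and signed
  condition difference maps.
- **`acoustic_gain`** — directional gain (dB re free field) per frequency
  and direction from the DFT magnitude of the HRIRs.
- **`neuron_model`** — model midbrain neuron (periodic cosine-exponential
  ITD tuning × Gaussian ILD tuning) and HRTF-derived per-frequency spatial
  tuning maps.
- **`tuning_analysis`** — tuning-curve metrics: Gaussian fit to the main
  ITD peak (best ITD, FWHM), half-height frequency bounds, best frequency,
  frontal classification (|best ITD| ≤ 30 µs), ITD↔azimuth conversion
  (3 µs/degree).
- **`population_stats`** — pooled Pearson regressions, pooled-variance
  slope/intercept t-tests, Mann–Whitney U (reported as min(U₁, U₂)), and
  the rank-biserial effect size r = |1 − 2U/(n₁n₂)|.
- **`cli`** — stagewise pipeline orchestration with deterministic seeding
  and a hashed run manifest.

Sign conventions: positive azimuth = right of the midline; positive ITD /
IPD = sound reaches the right ear first.

## Command line

```sh
# end-to-end demo on synthetic heads and neurons
owlspace run-all --seed 0 --out-dir runs/demo

# individual stages
owlspace simulate-hrtf --seed 0 --out-dir runs/demo
owlspace reliability --hrtf runs/demo/hrtf/normal --masker-amp 1.0 --reps 10 \
    --seed 0 --out-dir runs/demo
owlspace gain --hrtf runs/demo/hrtf/normal --freqs 500:10000:200 --out-dir runs/demo
owlspace neuron-map --hrtf runs/demo/hrtf/normal --freqs 3000:7000:1000 \
    --mu 0 --delta 0 --out-dir runs/demo
owlspace simulate-neurons --seed 0 --out-dir runs/demo
owlspace tuning-metrics --neurons runs/demo/neurons --out-dir runs/demo
owlspace group-stats --summaries runs/demo/summaries/neuron_summaries.tsv \
    --out-dir runs/demo
```

All subcommands accept `--config CONFIG.toml` (see
`tests/test_cli.py::TINY_TOML` for the schema), `--seed`, and `--out-dir`.
`run-all` writes a `run_manifest.json` with a SHA-256 per output; identical
config + seed reproduce identical hashes.

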