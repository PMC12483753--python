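# gsrstress

Stress quantification from galvanic skin response (GSR) streams.

Skin conductance rises with sympathetic arousal, so a wearable GSR sensor
can track stress — but its raw output is noisy and its scale differs from
person to person. `gsrstress` implements the complete processing chain a
wearable stress monitor runs between its ADC and its display, as a tested
Python library with a thin `gsr` command-line tool:

1. **Acquisition.** Raw 12-bit ADC counts A₁₂ ∈ [0, 4095] are mapped onto
   the sensor's 10-bit working scale:
   A₁₀ = A₁₂ · 1023/4095.
   A voltage-divider calibration curve converts a 10-bit serial reading
   (SPR) into skin resistance, given a no-contact baseline count `cal`:
   R = (1024 + 2·SPR) · 10000 / (cal − SPR) ohms, with conductance 1/R.
2. **Noise reduction.** A scalar Kalman filter with gain
   K = Eₚ/(Eₚ + Eₘ), state update X̂ ← X̂ + K·(z − X̂), and error update
   Eₚ ← (1 − K)·Eₚ. An optional process-noise term q (default 0) keeps the
   gain responsive for long-running streams.
3. **Personalized normalization.** Filtered readings are offset-corrected
   (A_cal = X̂ + C_offset) and rescaled against the subject's baseline
   range: GSR_norm = (A_cal − B_min)/(B_max − B_min) · 500, so one set of
   thresholds applies to every subject.
4. **Classification.** Four bands on the normalized scale
   (lower-exclusive / upper-inclusive): no stress ≤ 200 < minor ≤ 300 <
   high ≤ 400 < very high.

The package also ships a seedable synthetic GSR generator — tonic baseline,
drift, Poisson-arriving skin conductance responses (SCRs) whose rate scales
with the scheduled stress state, Gaussian sensor noise, per-sample
ground-truth labels — plus a bundled 16-subject cohort table of normalized
readings used as a classification fixture, and a 32×20 cohort generator.

## Worked example

`examples/03_replay_scheduled_stream.py` simulates a 2-minute session —
30 s rest, then 30 s each of minor, high and very-high stress at noise
σ = 20 counts — derives the calibration profile from the rest window, and
replays the stream through the full pipeline:

```
derived profile: b_min=299.68, b_max=399.61 (10-bit)
                  count  fraction
No stress           303  0.252500
Minor stress        297  0.247500
High stress         299  0.249167
Very high stress    301  0.250833

band agreement with the schedule: 99.5%
```

Each scheduled state occupies a quarter of the 1200-sample session; the
pipeline recovers the scheduled band on 99.5% of samples, losing a few
samples to filter lag after each transition. The other examples show
Kalman noise reduction on a resting stream (raw RMSE 3.48 → filtered
0.39 counts) and the bundled cohort table classifying perfectly into its
per-subject bands (e.g. all 14 of Person 1's readings very-high, all 14 of
Person 4's no-stress).

## Command line

```bash
gsr simulate --seed 1 --duration 60 --out stream.csv
gsr calibrate --in rest.csv --config config.toml      # writes b_min/b_max back
gsr replay --in stream.csv --config config.toml --out records.jsonl --summary summary.csv
gsr summarize --in records.jsonl
gsr simulate-cohort --subjects 32 --samples 20 --out cohort.csv
```

Configuration is one TOML file with `[acquisition]`, `[kalman]`,
`[calibration]` and `[pipeline]` sections (see `docs/methods.md` for all
keys and defaults). Exit codes: 0 success, 2 configuration error, 3 input
error.

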