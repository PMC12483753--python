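# Methods

## Signal model and processing chain

The package processes a univariate electrodermal signal sampled every
100 ms (configurable) as 12-bit ADC counts. The chain is strictly
feed-forward and per-sample:

    adc12  --(× 1023/4095)-->  adc10  --(Kalman)-->  x_est
    --(+ C_offset)-->  A_cal  --(min-max rescale)-->  GSR_norm  --(bands)--> level

### Bit-depth mapping

`map_12bit_to_10bit` returns the full-precision real value
`adc12 · 1023/4095`; it never truncates. Rounding (half to even) is a
display-layer option so the filter always consumes full precision. The
mapping is linear and strictly monotone; its two anchors are 0 → 0 and
4095 → 1023.

### Scalar Kalman filter

A one-dimensional filter with no control input:

    K      = E_p / (E_p + E_m)
    x_est' = x_est + K (z − x_est)
    E_p'   = (1 − K) E_p

`E_m` and `E_p` are scalar uncertainty magnitudes in signal units; only
their ratio enters the gain, so no variance-vs-standard-deviation
convention needs fixing. Two exact consequences used as test oracles:

* with `E_p0 = E_m` and an explicit initial state `x0`, the estimate after
  n updates is the arithmetic mean of `(x0, z1, …, zn)`;
* with constant `E_m > 0` the gain strictly decreases and `E_p → 0`, so
  the filter converges to a static average.

That convergence is the right behaviour for a short calibration window but
freezes the filter on long streams: once the gain is near zero the
estimate cannot track a genuine level change. `KalmanParams.q` (default 0)
adds process noise to `E_p` before each gain computation, which bounds the
steady-state gain away from zero. All hand-value and oracle tests run with
q = 0; streaming/recovery runs use q > 0 (we use q = E_m/4, giving a
steady-state gain ≈ 0.39 — residual noise roughly halved while level
changes are tracked within ~3 samples).

Initialization: `x0 = None` (default) seeds the state with the first
measurement (first output equals first sample, no update consumed);
an explicit `x0` treats every sample as an update.

Degenerate input `E_p = E_m = 0` is an error rather than a NaN.

### Baseline calibration and normalization

`A_cal = x_est + C_offset` (offset default 0), then

    GSR_norm = (A_cal − B_min) / (B_max − B_min) · 500.

Profiles require `B_max > B_min` strictly at construction. `normalize`
clamps its output to [0, 500] and flags when it clamped, keeping the
published scale consistent; `classify` nevertheless accepts any
non-negative value (the bundled cohort table contains readings of 501, so
the very-high band is open-ended above 400). Values are classified into
lower-exclusive/upper-inclusive bands: ≤200 no stress, (200, 300] minor,
(300, 400] high, >400 very high. A "moderate" label is treated as a
synonym of minor.

`estimate_baseline` is deliberately plain: min/max over a rest window of
at least 10 samples, optional guard factor `guard_eps` widening the top
end, no outlier rejection (a single spike inflates `B_max`; this
sensitivity is documented and tested rather than hidden).

### Resistance curve

For a 10-bit serial reading SPR below the no-contact calibration count:

    R = (1024 + 2·SPR) · 10000 / (cal − SPR)   [ohm],  G = 1/R.

10000 Ω is the divider's series resistor. The curve is strictly increasing
in SPR (numerator grows, denominator shrinks). `SPR ≥ cal` is a
calibration error, not infinity, to keep downstream arithmetic finite.

## Synthetic data generator

`simulate_subject_stream` emulates the statistical structure the pipeline
assumes, not sweat-gland biophysics. The noise-free trace is

    clean(t) = baseline + drift·t + tonic(level(t)) + Σ SCR pulses,

with samples = clean + Gaussian(0, noise_sd), rounded and clipped to
12 bits. One seeded `numpy` generator per stream; equal seeds give
bit-identical output.

* **Tonic stress term.** Each scheduled stress level raises the tonic
  level by a configurable amount expressed on the normalized scale
  (defaults: 0 / 250 / 350 / 450 for no/minor/high/very-high), converted
  to counts via the subject's dynamic range. Mid-band placement leaves
  ~50 normalized units of margin to the nearest threshold. A purely
  phasic encoding (event-rate only) cannot keep a stressed interval inside
  its band between events, so a tonic component is required for any
  classifier operating sample-wise on the normalized signal.
* **Phasic SCRs.** Pulses with a linear rise (1 s) and exponential decay
  (3 s time constant, truncated at 1%), exponential amplitudes (mean
  10 counts), arriving as a Poisson process (per-sample Bernoulli
  thinning) whose rate (3/min at rest) scales with the stress level
  (×1/2/3/4). This reproduces the qualitative electrodermal signature:
  higher arousal, more frequent conductance transients.
* **Defaults.** 100 ms cadence; resting baseline 1200 counts; dynamic
  range 400 counts (≈10% and ≈3.3% of full scale — mid-range placement
  keeps clipping out of play); noise σ = 10 counts, with 20 counts used
  as the stressed/noisy study condition.

What the generator does **not** model: motion artifacts, electrode
detachment, baseline wander from temperature/humidity, habituation, or
realistic SCR shape variability. Passing the recovery tests therefore
demonstrates internal consistency of the pipeline under its own
assumptions, not field accuracy on human data.

`simulate_cohort` draws per-subject normalized readings uniformly within
an assigned band, bands cycling very-high/high/minor/no-stress every four
subjects — the same layout as the bundled 16-subject table. The default
32 subjects × 20 samples yields 640 records.

### Bundled cohort table

`load_table2_fixture` returns a 16-column table of normalized readings
(four subjects per band). Persons 1–4 carry 14 readings; Persons 5–16
carry 13 (the missing cells load as NaN and are ignored by
`classify_table`). Count-based assertions use only the complete 14-reading
block.

## Calibration for the recovery study

`derive_profile` anchors `B_min` at the **mean** of the Kalman-filtered
rest window (an unbiased estimate of the resting tonic level; a min/max
anchor would shift with the realized noise extremes) and places `B_max`
one dynamic range above it on the 10-bit scale. The dynamic range plays
the role of the constant a one-off stress-induction calibration session
provides on a real device. The plain min/max estimator remains available
as `estimate_baseline` and backs the `gsr calibrate` command.

With this profile, filter settings `E_m = E_p0 = noise_sd` (10-bit scale)
and q = E_m/4, the full pipeline recovers the scheduled stress label on
≥ 97% of samples per seed at noise σ = 20 counts (the tested guarantee is
≥ 90% on every one of 50 seeds); losses are concentrated in the few
samples of filter lag after each level transition.

## Pipeline and CLI

`run_replay` applies the stages in fixed order, one record per input
sample, and accumulates per-stage wall time (read/filter/normalize/emit).
Timings are informational only — they depend on the host and are never
asserted. On-device sinks are replaced by JSONL/CSV writers and an
optional emit hook; `--realtime` sleeps to the configured cadence for
demos. Replay is deterministic: identical input and config give
byte-identical JSONL.

TOML configuration keys (one file, four sections):

| section         | key                  | default | meaning |
|-----------------|----------------------|---------|---------|
| `[acquisition]` | `serial_calibration` | 512     | no-contact baseline count (10-bit) |
|                 | `round_mapped`       | false   | display-layer rounding |
| `[kalman]`      | `e_m`                | 4.0     | measurement error, 10-bit counts |
|                 | `e_p0`               | 1.0     | initial estimated error |
|                 | `x0`                 | unset   | explicit initial state (unset = first measurement) |
|                 | `q`                  | 0.0     | process noise per step |
| `[calibration]` | `c_offset`           | 0.0     | additive offset |
|                 | `b_min`, `b_max`     | —       | subject baseline range (required) |
| `[pipeline]`    | `sample_period_ms`   | 100     | replay cadence |

The kalman defaults (`e_m = 4`, `e_p0 = 1` in 10-bit counts) are
documented working values for a moderately noisy sensor, not derived
constants; every quantitative test passes explicit parameters.

## Numerical and design choices

* Band boundaries are compared with plain floating-point `<=`; the
  partition is verified by an exhaustive 0.01-grid sweep over [0, 500].
* The filter's convex-combination property (`x_est'` between the prior
  estimate and the measurement) is asserted with a 1e-9 absolute slack to
  absorb rounding at the interval edges.
* Cohort band draws use `uniform(low, high)` over each band's open/closed
  interval; the probability of drawing an exact boundary is zero.
* Empty replay input is a warning and an empty output, not an error;
  empty filter input is an error (the filter has no state to return).
* Stage timings use `time.perf_counter()` deltas accumulated per stage;
  at 100 ms cadence the instrumentation overhead is negligible.

## Known limitations

* The recovery guarantee is specific to the generator's assumptions
  (stationary noise, step-like tonic shifts, known dynamic range); on real
  devices the dynamic range must come from a per-subject calibration
  session, and drift between calibration and use degrades normalization.
* `estimate_baseline`'s min/max is not robust to artifacts; robust
  alternatives (percentiles) are easy to layer on top but are not the
  documented default.
* The classifier is memoryless and sample-wise; no hysteresis or dwell
  time is applied at band boundaries, so a signal hovering at a threshold
  can flicker between adjacent bands.
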