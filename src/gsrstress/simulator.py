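"""Seedable synthetic GSR streams and cohorts, plus the bundled cohort table.

The subject-stream generator emulates the statistical structure the
processing pipeline assumes, in raw 12-bit ADC counts:

* a resting tonic baseline with optional slow linear drift;
* a per-level tonic elevation while a stress state is scheduled, sized so
  that — after the 10-bit mapping and baseline normalization against the
  subject's dynamic range — each state sits inside its stress band;
* phasic skin-conductance responses (SCRs): pulses with a linear rise and
  exponential decay, exponential amplitudes, arriving as a Poisson process
  whose rate scales with the scheduled stress level;
* additive Gaussian sensor noise, then rounding and clipping to 12 bits.

Every sample carries a ground-truth stress label, so parameter-recovery
and accuracy properties can score the full pipeline against the schedule.
A cohort generator emits per-subject normalized draws in a fixed band
layout (four bands cycling across subjects, mirroring the bundled table),
and ``load_table2_fixture`` returns the package's printed 16-subject
cohort table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .acquisition import ADC12_MAX, ADC_SCALE, RawSample, write_stream_csv
from .errors import ConfigError
from .kalman import KalmanParams, filter_series
from .normalize import CalibrationProfile, StressLevel

#: default tonic elevation per stress level, in normalized (0-500) units,
#: placed mid-band so band membership survives filtering and noise
DEFAULT_TONIC_NORM: Mapping[StressLevel, float] = {
    StressLevel.NO_STRESS: 0.0,
    StressLevel.MINOR: 250.0,
    StressLevel.HIGH: 350.0,
    StressLevel.VERY_HIGH: 450.0,
}

#: default SCR Poisson-rate multiplier per stress level
DEFAULT_RATE_SCALE: Mapping[StressLevel, float] = {
    StressLevel.NO_STRESS: 1.0,
    StressLevel.MINOR: 2.0,
    StressLevel.HIGH: 3.0,
    StressLevel.VERY_HIGH: 4.0,
}


@dataclass(frozen=True)
class SimulatorConfig:
    """Subject-stream generator settings (counts are 12-bit ADC units).

    The stream samples every ``sample_period_ms`` (default 100 ms).
    ``dynamic_range_adc12`` is the subject's full conductance swing: the
    count offset from the resting baseline that corresponds to the top of
    the normalized scale (500). ``stress_schedule`` lists non-overlapping
    ``(start_s, end_s, level)`` intervals; unscheduled time is NO_STRESS.
    """

    seed: int = 0
    duration_s: float = 60.0
    sample_period_ms: int = 100
    baseline_adc12: float = 1200.0
    dynamic_range_adc12: float = 400.0
    drift_per_min: float = 0.0
    scr_rate_per_min: float = 3.0
    scr_amplitude: float = 10.0
    scr_rise_s: float = 1.0
    scr_decay_s: float = 3.0
    noise_sd: float = 10.0
    stress_schedule: tuple[tuple[float, float, StressLevel], ...] = ()
    tonic_norm: Mapping[StressLevel, float] = field(
        default_factory=lambda: dict(DEFAULT_TONIC_NORM)
    )
    rate_scale: Mapping[StressLevel, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_SCALE)
    )

    def __post_init__(self) -> None:
        if self.sample_period_ms <= 0:
            raise ConfigError("sample_period_ms must be > 0")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.dynamic_range_adc12 <= 0:
            raise ConfigError("dynamic_range_adc12 must be > 0")
        if self.scr_rate_per_min < 0 or self.scr_amplitude < 0:
            raise ConfigError("SCR rate and amplitude must be >= 0")
        if self.scr_rise_s <= 0 or self.scr_decay_s <= 0:
            raise ConfigError("SCR rise/decay times must be > 0")
        normalized: list[tuple[float, float, StressLevel]] = []
        for start, end, level in self.stress_schedule:
            if isinstance(level, str):
                level = StressLevel.from_label(level)
            if not 0.0 <= start < end <= self.duration_s:
                raise ConfigError(
                    f"schedule interval ({start}, {end}) must lie inside "
                    f"[0, {self.duration_s}] with start < end"
                )
            normalized.append((float(start), float(end), level))
        normalized.sort()
        for (s0, e0, _), (s1, _, _) in zip(normalized, normalized[1:]):
            if s1 < e0:
                raise ConfigError("schedule intervals must not overlap")
        object.__setattr__(self, "stress_schedule", tuple(normalized))

    def ground_truth_profile(self) -> CalibrationProfile:
        """The calibration profile the generator's geometry implies: the
        resting baseline maps to 0 and baseline + dynamic range to 500,
        both on the 10-bit scale."""
        b_min = self.baseline_adc12 * ADC_SCALE
        return CalibrationProfile(
            b_min=b_min,
            b_max=b_min + self.dynamic_range_adc12 * ADC_SCALE,
        )


@dataclass(frozen=True)
class SyntheticStream:
    """Generator output: raw samples, the noise-free trace, and per-sample
    ground-truth stress labels (all equal length)."""

    t_ms: np.ndarray
    adc12: np.ndarray
    clean: np.ndarray
    labels: np.ndarray  # StressLevel values (int)
    config: SimulatorConfig

    def __len__(self) -> int:
        return int(self.t_ms.size)

    def to_raw_samples(self) -> list[RawSample]:
        return [
            RawSample(t_ms=int(t), adc12=int(a))
            for t, a in zip(self.t_ms, self.adc12)
        ]

    def to_csv(self, path: str | Path) -> None:
        write_stream_csv(self.to_raw_samples(), path)

    def level_at(self, i: int) -> StressLevel:
        return StressLevel(int(self.labels[i]))


def _scr_kernel(config: SimulatorConfig, dt_s: float) -> np.ndarray:
    """Unit-amplitude SCR pulse: linear rise over scr_rise_s, then
    exponential decay with time constant scr_decay_s (truncated at 1%)."""
    n_rise = max(int(round(config.scr_rise_s / dt_s)), 1)
    n_decay = max(int(round(config.scr_decay_s * np.log(100.0) / dt_s)), 1)
    rise = np.linspace(1.0 / n_rise, 1.0, n_rise)
    decay = np.exp(-np.arange(1, n_decay + 1) * dt_s / config.scr_decay_s)
    return np.concatenate([rise, decay])


def simulate_subject_stream(config: SimulatorConfig) -> SyntheticStream:
    """Generate one subject's raw GSR stream; identical seeds give
    bit-identical output."""
    rng = np.random.default_rng(config.seed)
    dt_s = config.sample_period_ms / 1000.0
    n = int(round(config.duration_s / dt_s))
    t_s = np.arange(n) * dt_s
    t_ms = (t_s * 1000.0).round().astype(np.int64)

    labels = np.full(n, int(StressLevel.NO_STRESS), dtype=np.int64)
    for start, end, level in config.stress_schedule:
        labels[(t_s >= start) & (t_s < end)] = int(level)

    tonic_counts = np.array(
        [config.tonic_norm[StressLevel(v)] for v in labels], dtype=float
    ) * (config.dynamic_range_adc12 / 500.0)
    clean = config.baseline_adc12 + config.drift_per_min * (t_s / 60.0) + tonic_counts

    # phasic SCRs: per-sample Bernoulli thinning of the level-scaled Poisson rate
    rate_hz = (
        config.scr_rate_per_min
        / 60.0
        * np.array([config.rate_scale[StressLevel(v)] for v in labels])
    )
    events = rng.random(n) < rate_hz * dt_s
    if events.any() and config.scr_amplitude > 0:
        kernel = _scr_kernel(config, dt_s)
        amplitudes = rng.exponential(config.scr_amplitude, size=int(events.sum()))
        phasic = np.zeros(n + kernel.size)
        for idx, amp in zip(np.flatnonzero(events), amplitudes):
            phasic[idx : idx + kernel.size] += amp * kernel
        clean = clean + phasic[:n]

    noisy = clean + rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else clean.copy()
    adc12 = np.clip(np.rint(noisy), 0, ADC12_MAX).astype(np.int64)
    return SyntheticStream(
        t_ms=t_ms, adc12=adc12, clean=clean, labels=labels, config=config
    )


def derive_profile(
    stream: SyntheticStream,
    params: KalmanParams,
    rest_end_s: float,
) -> CalibrationProfile:
    """Calibration profile from a stream's initial rest window.

    b_min is the mean of the Kalman-filtered rest window (an unbiased
    anchor for the resting tonic level); b_max places the subject's
    configured dynamic range above it on the 10-bit scale — the constant a
    one-off stress-induction calibration session would supply on a real
    device.
    """
    dt_s = stream.config.sample_period_ms / 1000.0
    n_rest = int(round(rest_end_s / dt_s))
    if n_rest < 10:
        raise ConfigError(
            f"rest window of {rest_end_s} s gives {n_rest} samples; need >= 10"
        )
    mapped = stream.adc12[:n_rest] * ADC_SCALE
    filtered, _ = filter_series(mapped, params)
    b_min = float(filtered.mean())
    span = stream.config.dynamic_range_adc12 * ADC_SCALE
    return CalibrationProfile(b_min=b_min, b_max=b_min + span)


# ---------------------------------------------------------------------------
# Cohort generation and the bundled printed cohort table


#: subject band layout of the bundled table: bands cycle every 4 subjects
TABLE2_BAND_CYCLE = (
    StressLevel.VERY_HIGH,
    StressLevel.HIGH,
    StressLevel.MINOR,
    StressLevel.NO_STRESS,
)

#: draw ranges (low, high) on the normalized scale per band
BAND_RANGES: Mapping[StressLevel, tuple[float, float]] = {
    StressLevel.NO_STRESS: (0.0, 200.0),
    StressLevel.MINOR: (200.0, 300.0),
    StressLevel.HIGH: (300.0, 400.0),
    StressLevel.VERY_HIGH: (400.0, 500.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: n_subjects x samples_per_subject normalized draws,
    bands assigned by cycling ``band_cycle`` across subjects."""

    n_subjects: int = 32
    samples_per_subject: int = 20
    seed: int = 0
    band_cycle: tuple[StressLevel, ...] = TABLE2_BAND_CYCLE

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.samples_per_subject < 1:
            raise ConfigError(
                "n_subjects and samples_per_subject must be >= 1"
            )
        if not self.band_cycle:
            raise ConfigError("band_cycle must be non-empty")


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort table.

    Returns (values, labels): values has one subject per column and
    ``samples_per_subject`` rows of normalized readings drawn uniformly
    within the subject's assigned band; labels carries the band name for
    every cell. Total record count is n_subjects * samples_per_subject.
    """
    rng = np.random.default_rng(config.seed)
    values: dict[str, np.ndarray] = {}
    labels: dict[str, list[str]] = {}
    for j in range(config.n_subjects):
        band = config.band_cycle[j % len(config.band_cycle)]
        low, high = BAND_RANGES[band]
        col = f"Subject {j + 1}"
        values[col] = rng.uniform(low, high, size=config.samples_per_subject)
        labels[col] = [band.label] * config.samples_per_subject
    return pd.DataFrame(values), pd.DataFrame(labels)


#: band of each bundled-table column ("Person 1" ... "Person 16")
TABLE2_BANDS: Mapping[str, StressLevel] = {
    f"Person {i + 1}": TABLE2_BAND_CYCLE[i % 4] for i in range(16)
}


def load_table2_fixture() -> pd.DataFrame:
    """The bundled 16-subject cohort table, exactly as printed.

    Columns "Person 1" ... "Person 16"; Persons 1-4 carry 14 readings,
    Persons 5-16 carry 13 (missing cells are NaN). Column band
    assignments are in :data:`TABLE2_BANDS`.
    """
    resource = importlib.resources.files("gsrstress.data").joinpath("table2.csv")
    with importlib.resources.as_file(resource) as path:
        return pd.read_csv(path, encoding="utf-8")
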