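"""End-to-end replay engine: acquisition -> Kalman -> normalization ->
classification, with per-stage timing instrumentation and summaries.

``run_replay`` applies the stages in fixed order to every sample of a raw
stream and emits one :class:`PipelineRecord` per input sample, plus wall
timings per stage (reported for profiling only — they depend on the host
and are never part of any correctness contract). On-device sinks (display,
cloud upload) are replaced by file sinks: JSONL and CSV writers, and an
optional per-record emit hook.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, RawSample, map_12bit_to_10bit
from .errors import ConfigError, InputError
from .kalman import KalmanParams, initial_state, kalman_step
from .normalize import (
    CalibrationProfile,
    StressLevel,
    apply_offset,
    classify,
    normalize,
)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage settings for one subject/run."""

    acquisition: AcquisitionConfig
    kalman: KalmanParams
    calibration: CalibrationProfile
    sample_period_ms: int = 100

    def __post_init__(self) -> None:
        if self.sample_period_ms <= 0:
            raise ConfigError("sample_period_ms must be > 0")


@dataclass(frozen=True)
class PipelineRecord:
    """One sample traced through every stage."""

    t_ms: int
    adc12: int
    adc10: float
    x_est: float
    gsr_norm: float
    clamped: bool
    level: StressLevel

    def to_dict(self) -> dict:
        return {
            "t_ms": self.t_ms,
            "adc12": self.adc12,
            "adc10": self.adc10,
            "x_est": self.x_est,
            "gsr_norm": self.gsr_norm,
            "clamped": self.clamped,
            "level": self.level.label,
        }


@dataclass
class StageTimings:
    """Cumulative per-stage wall time, milliseconds. Informational only."""

    read_ms: float = 0.0
    filter_ms: float = 0.0
    normalize_ms: float = 0.0
    emit_ms: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "read_ms": self.read_ms,
            "filter_ms": self.filter_ms,
            "normalize_ms": self.normalize_ms,
            "emit_ms": self.emit_ms,
        }


def run_replay(
    samples: Sequence[RawSample],
    config: PipelineConfig,
    *,
    emit: Callable[[PipelineRecord], None] | None = None,
    realtime: bool = False,
) -> tuple[list[PipelineRecord], StageTimings]:
    """Replay a raw stream through the full pipeline.

    Stages per sample, in order: bit-depth mapping, Kalman update,
    offset + normalization + band assignment, then the optional emit hook.
    Deterministic given identical input and config. ``realtime`` sleeps to
    the configured cadence between samples (demo use only).
    """
    timings = StageTimings()
    records: list[PipelineRecord] = []
    state = None
    for i, sample in enumerate(samples):
        t0 = time.perf_counter()
        adc10 = map_12bit_to_10bit(sample.adc12)
        t1 = time.perf_counter()
        if state is None:
            state = initial_state(adc10, config.kalman)
            if config.kalman.x0 is not None:
                state = kalman_step(state, adc10, config.kalman)
        else:
            state = kalman_step(state, adc10, config.kalman)
        t2 = time.perf_counter()
        reading = normalize(apply_offset(state.x_est, config.calibration), config.calibration)
        level = classify(reading.gsr_norm)
        t3 = time.perf_counter()
        record = PipelineRecord(
            t_ms=sample.t_ms,
            adc12=sample.adc12,
            adc10=adc10,
            x_est=state.x_est,
            gsr_norm=reading.gsr_norm,
            clamped=reading.clamped,
            level=level,
        )
        records.append(record)
        if emit is not None:
            emit(record)
        t4 = time.perf_counter()
        timings.read_ms += (t1 - t0) * 1e3
        timings.filter_ms += (t2 - t1) * 1e3
        timings.normalize_ms += (t3 - t2) * 1e3
        timings.emit_ms += (t4 - t3) * 1e3
        if realtime and i + 1 < len(samples):
            time.sleep(config.sample_period_ms / 1000.0)
    return records, timings


def summarize_levels(records: Sequence[PipelineRecord]) -> pd.DataFrame:
    """Counts and fractions per stress band over a record sequence.

    Counts always sum to the record count; fractions sum to 1 (or are all
    zero for empty input).
    """
    counts = {lv.label: 0 for lv in StressLevel}
    for r in records:
        counts[r.level.label] += 1
    total = len(records)
    return pd.DataFrame(
        {
            "count": list(counts.values()),
            "fraction": [c / total if total else 0.0 for c in counts.values()],
        },
        index=list(counts.keys()),
    )


def percent_agreement(
    predicted: Sequence[StressLevel | int], truth: Sequence[StressLevel | int]
) -> float:
    """100 x (matching positions) / length for two equal-length label
    sequences."""
    p = np.asarray([int(v) for v in predicted])
    t = np.asarray([int(v) for v in truth])
    if p.size != t.size:
        raise InputError(
            f"label sequences differ in length ({p.size} vs {t.size})"
        )
    if p.size == 0:
        raise InputError("label sequences must be non-empty")
    return 100.0 * float(np.mean(p == t))


# ---------------------------------------------------------------------------
# Record sinks


def write_records_jsonl(records: Iterable[PipelineRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_records_jsonl(path: str | Path) -> list[PipelineRecord]:
    records = []
    try:
        fh = open(path, encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read records {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
                records.append(
                    PipelineRecord(
                        t_ms=int(d["t_ms"]),
                        adc12=int(d["adc12"]),
                        adc10=float(d["adc10"]),
                        x_est=float(d["x_est"]),
                        gsr_norm=float(d["gsr_norm"]),
                        clamped=bool(d["clamped"]),
                        level=StressLevel.from_label(d["level"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise InputError(
                    f"malformed record at line {lineno} of {path}: {exc}"
                ) from exc
    return records


def write_records_csv(records: Iterable[PipelineRecord], path: str | Path) -> None:
    pd.DataFrame([r.to_dict() for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stress-label recovery on synthetic streams (simulation study helper)


def evaluate_label_recovery(
    sim_config,
    *,
    kalman_params: KalmanParams | None = None,
    rest_end_s: float = 10.0,
) -> float:
    """Percent of samples whose pipeline band matches the schedule's label.

    Simulates a subject stream, derives the calibration profile from the
    initial rest window, replays the full pipeline, and scores band
    agreement against the stream's ground-truth labels. The default filter
    uses e_m equal to the noise level on the 10-bit scale and a small
    process-noise term so the gain stays responsive to level changes.
    """
    from .acquisition import ADC_SCALE
    from .simulator import derive_profile, simulate_subject_stream

    stream = simulate_subject_stream(sim_config)
    if kalman_params is None:
        e_m = max(sim_config.noise_sd * ADC_SCALE, 1e-6)
        kalman_params = KalmanParams(e_m=e_m, e_p0=e_m, q=0.25 * e_m)
    profile = derive_profile(stream, kalman_params, rest_end_s)
    config = PipelineConfig(
        acquisition=AcquisitionConfig(),
        kalman=kalman_params,
        calibration=profile,
        sample_period_ms=sim_config.sample_period_ms,
    )
    records, _ = run_replay(stream.to_raw_samples(), config)
    predicted = [r.level for r in records]
    return percent_agreement(predicted, stream.labels)
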