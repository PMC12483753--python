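"""Baseline calibration, dynamic range normalization, stress bands.

Filtered readings are adjusted by a per-subject calibration offset,

    A_cal = x_est + C_offset

then rescaled onto a common 0-500 scale using the subject's baseline
minimum and maximum:

    GSR_norm = (A_cal - B_min) / (B_max - B_min) * 500

so the same classification thresholds apply to every subject regardless
of individual skin properties. The four stress bands on the normalized
scale are lower-exclusive / upper-inclusive:

    No stress        GSR_norm <= 200
    Minor stress     200 < GSR_norm <= 300
    High stress      300 < GSR_norm <= 400
    Very high stress GSR_norm > 400

Normalization clamps its output to [0, 500] (and flags when it did), but
classification accepts any non-negative value so unclamped upstream
readings above 500 remain classifiable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigError, DomainError, InputError

NORM_SCALE = 500.0

#: band upper edges on the normalized scale (upper-inclusive)
BAND_EDGES = (200.0, 300.0, 400.0)


class StressLevel(enum.IntEnum):
    """Four-band stress classification, totally ordered by severity."""

    NO_STRESS = 0
    MINOR = 1
    HIGH = 2
    VERY_HIGH = 3

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "StressLevel":
        key = label.strip().lower()
        for level, text in _LABELS.items():
            if key in (text.lower(), level.name.lower(), level.name.lower().replace("_", " ")):
                return level
        # "moderate" appears as a synonym for the minor band
        if key == "moderate":
            return cls.MINOR
        if key in ("low", "low stress", "no"):
            return cls.NO_STRESS
        raise ConfigError(f"unknown stress level label {label!r}")


_LABELS = {
    StressLevel.NO_STRESS: "No stress",
    StressLevel.MINOR: "Minor stress",
    StressLevel.HIGH: "High stress",
    StressLevel.VERY_HIGH: "Very high stress",
}


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-subject calibration constants.

    c_offset : additive correction applied to filtered readings (may be
        negative). Default 0.
    b_min, b_max : subject baseline minimum / maximum in signal (10-bit)
        units; b_max must strictly exceed b_min.
    """

    b_min: float
    b_max: float
    c_offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("b_min", "b_max", "c_offset"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v}")
        if not self.b_max > self.b_min:
            raise ConfigError(
                f"b_max must strictly exceed b_min (got b_min={self.b_min}, "
                f"b_max={self.b_max})"
            )


@dataclass(frozen=True)
class StressReading:
    """A normalized value on the 0-500 scale with its stress band.

    ``clamped`` is True when the raw normalization fell outside [0, 500];
    ``level`` is None until classification is applied.
    """

    gsr_norm: float
    clamped: bool
    level: StressLevel | None = None


def apply_offset(x_est: float, profile: CalibrationProfile) -> float:
    """Calibrated reading A_cal = x_est + c_offset."""
    if not math.isfinite(x_est):
        raise InputError(f"x_est must be finite, got {x_est}")
    return x_est + profile.c_offset


def normalize(a_calibrated: float, profile: CalibrationProfile) -> StressReading:
    """Rescale a calibrated reading onto [0, 500] using the subject baseline.

    b_min maps to 0 and b_max to 500; values outside the baseline range are
    clamped and flagged. The level field is left unset.
    """
    if not math.isfinite(a_calibrated):
        raise InputError(f"a_calibrated must be finite, got {a_calibrated}")
    raw = (a_calibrated - profile.b_min) / (profile.b_max - profile.b_min) * NORM_SCALE
    clamped = not 0.0 <= raw <= NORM_SCALE
    return StressReading(
        gsr_norm=min(max(raw, 0.0), NORM_SCALE), clamped=clamped, level=None
    )


def classify(gsr_norm: float) -> StressLevel:
    """Assign the stress band for a normalized value.

    Bands are lower-exclusive / upper-inclusive; VERY_HIGH is open-ended
    above 400 so unclamped values beyond 500 classify rather than error.
    Negative input is outside the normalized domain.
    """
    if not math.isfinite(gsr_norm) or gsr_norm < 0:
        raise DomainError(
            f"gsr_norm must be a finite non-negative value, got {gsr_norm}"
        )
    if gsr_norm <= BAND_EDGES[0]:
        return StressLevel.NO_STRESS
    if gsr_norm <= BAND_EDGES[1]:
        return StressLevel.MINOR
    if gsr_norm <= BAND_EDGES[2]:
        return StressLevel.HIGH
    return StressLevel.VERY_HIGH


def score(x_est: float, profile: CalibrationProfile) -> StressReading:
    """Offset -> normalize -> classify in one call; returns a completed
    :class:`StressReading`."""
    reading = normalize(apply_offset(x_est, profile), profile)
    return StressReading(
        gsr_norm=reading.gsr_norm,
        clamped=reading.clamped,
        level=classify(reading.gsr_norm),
    )


def estimate_baseline(
    filtered_rest_samples: Sequence[float] | np.ndarray,
    *,
    min_samples: int = 10,
    guard_eps: float = 0.0,
) -> tuple[float, float]:
    """Derive (b_min, b_max) from a resting calibration window.

    Plain min/max over the window, with an optional guard factor widening
    the top end: b_max = max + guard_eps * (max - min). No outlier
    rejection is applied, so a single spike inflates b_max — callers
    wanting robustness should pre-clean the window.
    """
    x = np.asarray(filtered_rest_samples, dtype=float)
    if x.size < min_samples:
        raise CalibrationError(
            f"insufficient calibration window: {x.size} samples, "
            f"need at least {min_samples}"
        )
    if not np.all(np.isfinite(x)):
        raise InputError("calibration window contains non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise CalibrationError(
            "degenerate baseline: calibration window is constant"
        )
    return lo, hi + guard_eps * (hi - lo)


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Count, per subject column, the values in each stress band.

    Accepts a DataFrame of normalized values with subject-labelled columns;
    missing cells (NaN from ragged columns) are ignored, any other
    non-numeric cell raises naming the row and column. Returns a DataFrame
    indexed by band label whose per-column counts sum to the column's
    non-missing length.
    """
    counts = pd.DataFrame(
        0, index=[lv.label for lv in StressLevel], columns=table.columns, dtype=int
    )
    for col in table.columns:
        for row_idx, value in table[col].items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            try:
                v = float(value)
                if math.isnan(v):
                    continue
            except (TypeError, ValueError) as exc:
                raise InputError(
                    f"non-numeric cell at row {row_idx!r}, column {col!r}: "
                    f"{value!r}"
                ) from exc
            counts.loc[classify(v).label, col] += 1
    return counts


def read_table_csv(path) -> pd.DataFrame:
    """Read a subject-labelled table of normalized values from CSV."""
    try:
        return pd.read_csv(path, encoding="utf-8")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise InputError(f"cannot read table CSV {path}: {exc}") from exc


def write_counts_csv(counts: pd.DataFrame, path) -> None:
    """Write per-band counts with the band labels as the first column."""
    counts.to_csv(path, index_label="level")
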