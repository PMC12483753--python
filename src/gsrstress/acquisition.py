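"""Raw-sensor acquisition: bit-depth mapping and the skin-resistance curve.

A Grove-style GSR sensor is read by a 12-bit ADC (counts 0-4095). All
downstream processing works on a 10-bit scale (0-1023), the native range of
the sensor's serial protocol, so the first step is the linear mapping

    A10 = A12 * 1023 / 4095

The sensor sits in a voltage divider with a 10 kOhm series resistor; once a
no-contact baseline count (the *serial calibration* value) is known, the
skin resistance follows from the divider equation

    R = (1024 + 2 * SPR) * 10000 / (cal - SPR)      [ohms]

where SPR is the current serial-port reading. Skin conductance, the
physiological quantity that rises with sympathetic arousal, is 1/R.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DomainError, InputError

ADC12_MAX = 4095
ADC10_MAX = 1023
#: linear scale factor from 12-bit to 10-bit counts
ADC_SCALE = ADC10_MAX / ADC12_MAX

#: series resistor of the sensor's voltage divider, ohms
DIVIDER_RESISTANCE_OHM = 10_000


@dataclass(frozen=True)
class RawSample:
    """One timestamped 12-bit ADC reading.

    Parameters
    ----------
    t_ms : int
        Timestamp in milliseconds. Strictly increasing within a stream.
    adc12 : int
        Raw ADC count, 0-4095.
    """

    t_ms: int
    adc12: int

    def __post_init__(self) -> None:
        if not isinstance(self.adc12, Integral):
            raise DomainError(
                f"adc12 must be an integer count, got {self.adc12!r}"
            )
        if not 0 <= self.adc12 <= ADC12_MAX:
            raise DomainError(
                f"adc12 must be in [0, {ADC12_MAX}], got {self.adc12}"
            )


@dataclass(frozen=True)
class MappedSample:
    """A 12-bit reading rescaled onto the 10-bit (0-1023) working scale."""

    t_ms: int
    adc10: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adc10 <= ADC10_MAX:
            raise DomainError(
                f"adc10 must be in [0, {ADC10_MAX}], got {self.adc10}"
            )


@dataclass(frozen=True)
class ResistanceEstimate:
    """Skin resistance (ohms) and its reciprocal conductance (siemens)."""

    resistance: float
    conductance: float


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition-stage settings.

    serial_calibration is the no-contact baseline count on the 10-bit
    scale; round_mapped enables display-layer rounding (half to even) of
    mapped values — the filter always consumes full precision.
    """

    serial_calibration: int = 512
    round_mapped: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.serial_calibration <= ADC10_MAX:
            from .errors import ConfigError

            raise ConfigError(
                "serial_calibration must be in (0, "
                f"{ADC10_MAX}], got {self.serial_calibration}"
            )


def map_12bit_to_10bit(adc12: int) -> float:
    """Map a raw 12-bit count (0-4095) onto the 10-bit scale (0-1023).

    Returns the full-precision real value ``adc12 * 1023 / 4095``; rounding,
    if wanted for display, is applied separately.

    Raises
    ------
    DomainError
        If ``adc12`` is not an integer in [0, 4095].
    """
    if isinstance(adc12, bool) or not isinstance(adc12, Integral):
        raise DomainError(
            f"adc12 must be an integer in [0, {ADC12_MAX}], got {adc12!r}"
        )
    if not 0 <= adc12 <= ADC12_MAX:
        raise DomainError(
            f"adc12 must be an integer in [0, {ADC12_MAX}], got {adc12}"
        )
    return adc12 * ADC10_MAX / ADC12_MAX


def map_series(adc12: Sequence[int] | np.ndarray) -> np.ndarray:
    """Vectorised :func:`map_12bit_to_10bit` for a whole stream."""
    arr = np.asarray(adc12)
    if arr.size == 0:
        return arr.astype(float)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise DomainError("adc12 series must contain integer counts")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > ADC12_MAX:
        raise DomainError(
            f"adc12 series values must lie in [0, {ADC12_MAX}]"
        )
    return arr * (ADC10_MAX / ADC12_MAX)


def round_display(adc10: float) -> int:
    """Display-layer rounding of a mapped value (round half to even)."""
    return int(np.rint(adc10))


def skin_resistance(
    serial_port_reading: int, config: AcquisitionConfig
) -> ResistanceEstimate:
    """Estimate skin resistance from a 10-bit serial reading.

    Implements the Grove voltage-divider calibration curve

        R = ((1024 + 2 * SPR) * 10000) / (cal - SPR)

    and returns conductance as the exact reciprocal. The reading must be
    strictly below the calibration baseline, otherwise the divider equation
    has a non-positive denominator and resistance is undefined.
    """
    spr = serial_port_reading
    if isinstance(spr, bool) or not isinstance(spr, Integral):
        raise DomainError(
            f"serial_port_reading must be an integer, got {spr!r}"
        )
    if not 0 <= spr <= ADC10_MAX:
        raise DomainError(
            f"serial_port_reading must be in [0, {ADC10_MAX}], got {spr}"
        )
    if spr >= config.serial_calibration:
        raise CalibrationError(
            "reading at or above calibration baseline; resistance undefined "
            f"(reading={spr}, calibration={config.serial_calibration})"
        )
    resistance = ((1024 + 2 * spr) * DIVIDER_RESISTANCE_OHM) / (
        config.serial_calibration - spr
    )
    return ResistanceEstimate(resistance=resistance, conductance=1.0 / resistance)


# ---------------------------------------------------------------------------
# CSV stream I/O — columns ``t_ms,adc12``, header required, UTF-8.

STREAM_COLUMNS = ("t_ms", "adc12")


def read_stream_csv(path: str | Path) -> list[RawSample]:
    """Read a raw stream from CSV, validating schema and invariants.

    Rows must carry integer ``t_ms`` (strictly increasing) and integer
    ``adc12`` in [0, 4095]. Errors name the offending line (1-based,
    counting the header as line 1).
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise InputError(f"cannot read stream CSV {path}: {exc}") from exc
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(
            f"stream CSV {path} is missing required column(s) {missing}; "
            f"expected header {','.join(STREAM_COLUMNS)}"
        )
    samples: list[RawSample] = []
    prev_t: int | None = None
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        try:
            t = int(row.t_ms)
            adc = row.adc12
            if float(adc) != int(adc):
                raise ValueError(f"non-integer adc12 {adc!r}")
            sample = RawSample(t_ms=t, adc12=int(adc))
        except (TypeError, ValueError, DomainError) as exc:
            raise InputError(f"malformed stream row at line {line}: {exc}") from exc
        if prev_t is not None and t <= prev_t:
            raise InputError(
                f"timestamps must be strictly increasing; line {line} has "
                f"t_ms={t} after {prev_t}"
            )
        prev_t = t
        samples.append(sample)
    return samples


def write_stream_csv(samples: Iterable[RawSample], path: str | Path) -> None:
    """Write a raw stream as ``t_ms,adc12`` CSV."""
    df = pd.DataFrame(
        [(s.t_ms, s.adc12) for s in samples], columns=list(STREAM_COLUMNS)
    )
    df.to_csv(path, index=False)
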