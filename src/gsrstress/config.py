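"""TOML configuration: one file with ``[acquisition]``, ``[kalman]``,
``[calibration]`` and ``[pipeline]`` sections.

All keys are optional except the calibration baseline (``b_min``/``b_max``
have no sensible universal default — they are per-subject). Keys and
defaults:

    [acquisition]  serial_calibration = 512, round_mapped = false
    [kalman]       e_m = 4.0, e_p0 = 1.0, q = 0.0, x0 = (first measurement)
    [calibration]  c_offset = 0.0, b_min, b_max
    [pipeline]     sample_period_ms = 100
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .acquisition import AcquisitionConfig
from .errors import ConfigError
from .kalman import KalmanParams
from .normalize import CalibrationProfile
from .pipeline import PipelineConfig

_KNOWN_KEYS = {
    "acquisition": {"serial_calibration", "round_mapped"},
    "kalman": {"e_m", "e_p0", "x0", "q"},
    "calibration": {"c_offset", "b_min", "b_max"},
    "pipeline": {"sample_period_ms"},
}


def _section(data: dict, name: str) -> dict:
    section = data.get(name, {})
    if not isinstance(section, dict):
        raise ConfigError(f"[{name}] must be a table")
    unknown = set(section) - _KNOWN_KEYS[name]
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in [{name}]; "
            f"valid keys: {sorted(_KNOWN_KEYS[name])}"
        )
    return section


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a TOML file."""
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"malformed TOML in {path}: {exc}") from exc

    unknown_sections = set(data) - set(_KNOWN_KEYS)
    if unknown_sections:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown_sections)} in {path}"
        )

    acq = _section(data, "acquisition")
    kal = _section(data, "kalman")
    cal = _section(data, "calibration")
    pipe = _section(data, "pipeline")

    for key in ("b_min", "b_max"):
        if key not in cal:
            raise ConfigError(
                f"[calibration] must define {key} (per-subject baseline)"
            )
    try:
        return PipelineConfig(
            acquisition=AcquisitionConfig(
                serial_calibration=int(acq.get("serial_calibration", 512)),
                round_mapped=bool(acq.get("round_mapped", False)),
            ),
            kalman=KalmanParams(
                e_m=float(kal.get("e_m", 4.0)),
                e_p0=float(kal.get("e_p0", 1.0)),
                x0=float(kal["x0"]) if "x0" in kal else None,
                q=float(kal.get("q", 0.0)),
            ),
            calibration=CalibrationProfile(
                b_min=float(cal["b_min"]),
                b_max=float(cal["b_max"]),
                c_offset=float(cal.get("c_offset", 0.0)),
            ),
            sample_period_ms=int(pipe.get("sample_period_ms", 100)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid value in {path}: {exc}") from exc


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return repr(value) if not isinstance(value, str) else f'"{value}"'


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a pipeline configuration back to TOML (scalar keys only)."""
    lines = [
        "[acquisition]",
        f"serial_calibration = {config.acquisition.serial_calibration}",
        f"round_mapped = {_fmt(config.acquisition.round_mapped)}",
        "",
        "[kalman]",
        f"e_m = {_fmt(float(config.kalman.e_m))}",
        f"e_p0 = {_fmt(float(config.kalman.e_p0))}",
    ]
    if config.kalman.x0 is not None:
        lines.append(f"x0 = {_fmt(float(config.kalman.x0))}")
    lines += [
        f"q = {_fmt(float(config.kalman.q))}",
        "",
        "[calibration]",
        f"c_offset = {_fmt(float(config.calibration.c_offset))}",
        f"b_min = {_fmt(float(config.calibration.b_min))}",
        f"b_max = {_fmt(float(config.calibration.b_max))}",
        "",
        "[pipeline]",
        f"sample_period_ms = {config.sample_period_ms}",
        "",
    ]
    Path(path).write_text("\n".join(lines), encoding="utf-8")
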