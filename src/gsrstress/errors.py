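"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`ConfigError` -> 2,
:class:`InputError` -> 3.
"""


class GsrError(Exception):
    """Base class for all package errors."""

    exit_code: int = 1


class ConfigError(GsrError, ValueError):
    """Invalid configuration: bad parameter values, malformed config files."""

    exit_code = 2


class CalibrationError(ConfigError):
    """Calibration-specific failure (degenerate baseline, reading at or
    above the serial calibration baseline, too-short rest window)."""


class InputError(GsrError, ValueError):
    """Invalid runtime input: malformed stream rows, out-of-range samples,
    non-finite measurements, mismatched sequence lengths."""

    exit_code = 3


class DomainError(InputError):
    """A value outside the mathematical domain of an operation."""
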