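"""Scalar Kalman filter for GSR noise reduction.

The filter keeps a single state estimate ``x_est`` with uncertainty
``e_p`` and, for each measurement ``z`` with measurement error ``e_m``:

    K      = e_p / (e_p + e_m)          (gain)
    x_est' = x_est + K * (z - x_est)    (state update)
    e_p'   = (1 - K) * e_p              (error update)

With no process noise the gain decays to zero and the estimate converges
to a weighted average of everything seen so far; in the special case
``e_p0 == e_m`` the estimate after n updates is exactly the arithmetic
mean of the initial state and the n measurements. An optional additive
process-noise term ``q`` (added to e_p before the gain is computed) keeps
the gain bounded away from zero so the filter can track level changes in
long-running streams; the default q = 0 reproduces the equations above
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError, InputError


@dataclass(frozen=True)
class KalmanParams:
    """Filter tuning parameters.

    e_m : measurement error, same units as the signal (> 0 normally;
        0 means measurements are trusted fully).
    e_p0 : initial estimated error (> 0).
    x0 : explicit initial state; None selects the first-measurement
        policy (the filter is seeded with the first sample).
    q : additive process noise per step (>= 0, default 0).
    """

    e_m: float = 4.0
    e_p0: float = 1.0
    x0: float | None = None
    q: float = 0.0

    def __post_init__(self) -> None:
        if self.e_m < 0:
            raise ConfigError(f"e_m must be >= 0, got {self.e_m}")
        if self.e_p0 <= 0:
            raise ConfigError(f"e_p0 must be > 0, got {self.e_p0}")
        if self.q < 0:
            raise ConfigError(f"q must be >= 0, got {self.q}")
        if self.x0 is not None and not math.isfinite(self.x0):
            raise ConfigError(f"x0 must be finite, got {self.x0}")


@dataclass(frozen=True)
class KalmanState:
    """Running filter state: estimate, error estimate, last gain, step count."""

    x_est: float
    e_p: float
    k_last: float = 0.0
    n_steps: int = 0


def kalman_gain(e_p: float, e_m: float) -> float:
    """Gain K = e_p / (e_p + e_m), the weight given to a new measurement.

    Raises :class:`DomainError` for negative errors and for the degenerate
    e_p = e_m = 0 case (the filter has no information to weigh).
    """
    if e_p < 0 or e_m < 0:
        raise DomainError(f"error estimates must be >= 0, got e_p={e_p}, e_m={e_m}")
    if e_p == 0 and e_m == 0:
        raise DomainError("degenerate filter: e_p and e_m are both zero")
    return e_p / (e_p + e_m)


def kalman_step(state: KalmanState, z: float, params: KalmanParams) -> KalmanState:
    """Consume one measurement and return the updated state.

    The updated estimate always lies between the previous estimate and the
    measurement (a convex combination weighted by the gain).
    """
    if not math.isfinite(z):
        raise InputError(f"measurement must be finite, got {z}")
    e_p_pred = state.e_p + params.q
    k = kalman_gain(e_p_pred, params.e_m)
    x_new = state.x_est + k * (z - state.x_est)
    e_p_new = (1.0 - k) * e_p_pred
    return KalmanState(
        x_est=x_new, e_p=e_p_new, k_last=k, n_steps=state.n_steps + 1
    )


def initial_state(first_measurement: float, params: KalmanParams) -> KalmanState:
    """Initial state under the configured x0 policy.

    With an explicit x0 the first measurement is treated as an ordinary
    update later; under the first-measurement policy the state is seeded
    directly with the sample.
    """
    x0 = params.x0 if params.x0 is not None else first_measurement
    return KalmanState(x_est=x0, e_p=params.e_p0, k_last=0.0, n_steps=0)


def filter_series(
    samples: Sequence[float] | np.ndarray, params: KalmanParams
) -> tuple[np.ndarray, KalmanState]:
    """Filter a whole series; element i of the output is x_est after
    consuming sample i.

    Under the first-measurement policy the first output equals the first
    sample (the seed, no update); with explicit x0 every sample is an
    update. Returns the filtered array and the final state.
    """
    z = np.asarray(samples, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise InputError("filter_series requires a non-empty 1-D sequence")
    if not np.all(np.isfinite(z)):
        raise InputError("filter_series requires finite measurements")

    out = np.empty_like(z)
    state = initial_state(z[0], params)
    start = 0
    if params.x0 is None:
        out[0] = state.x_est
        start = 1
    for i in range(start, z.size):
        state = kalman_step(state, z[i], params)
        out[i] = state.x_est
    return out, state
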