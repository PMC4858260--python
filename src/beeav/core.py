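"""Rate-coded unit dynamics.

The whole model is built from two first-order units, stepped with forward
Euler at a fixed resolution (0.1 ms by default):

* the leaky integrator neural unit (LIN), ``da/dt = (-a + sum(x)) / tau`` —
  a low-pass filter whose activity ``a`` stands in for a firing rate;
* the adaptive LIN modelling photoreceptor / lamina adaptation, a LIN with a
  subtractive adaptation current so that its steady-state response to any
  constant luminance is zero (a pure change detector).

Fixed axonal delays are modelled by a sample-aligned ring buffer, and the
four rectification modes convert the signed adaptive output into the
onset-only / offset-only / full-wave signals carried by spiking neurons.

All functions accept scalars or numpy arrays for the state, so a whole
retinotopic array of identical units can be stepped in one call.  Time
constants and ``dt`` are in milliseconds throughout.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "LINState",
    "AdaptiveLINState",
    "DelayLine",
    "RectifierMode",
    "step_lin",
    "lin_update",
    "step_adaptive_lin",
    "adaptive_lin_update",
    "rectify",
    "step_delay_line",
]


class ConfigurationError(ValueError):
    """Raised for invalid unit, stimulus or system configuration."""


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ConfigurationError(f"{name} must be > 0, got {value!r}")


@dataclass
class LINState:
    """Leaky integrator neural unit: activity ``a`` with time constant ``tau`` (ms)."""

    a: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("tau", self.tau)


@dataclass
class AdaptiveLINState:
    """Adaptive photoreceptor unit.

    ``a_pr`` is the output activity, ``alpha`` the adaptation current.  For a
    held input x the fixed point is ``alpha -> x`` and ``a_pr -> 0``, so only
    luminance *changes* are transmitted.
    """

    a_pr: float = 0.0
    alpha: float = 0.0
    tau_pr: float = 8.0
    tau_alpha: float = 15.0

    def __post_init__(self) -> None:
        _check_positive("tau_pr", self.tau_pr)
        _check_positive("tau_alpha", self.tau_alpha)


class RectifierMode(str, enum.Enum):
    """How the signed adaptive-unit output is converted for transmission."""

    NONE = "none"
    ONSET_ONLY = "onset_only"
    OFFSET_ONLY = "offset_only"
    FULL = "full"


def lin_update(a, input_sum, tau: float, dt: float, *, tau_multiplies: bool = False):
    """One forward-Euler step of the LIN equation; array-friendly.

    ``tau_multiplies=True`` selects the literal reading in which the rate of
    change is multiplied rather than divided by tau (kept only for
    comparison; the divisor reading is the model's).
    """
    _check_positive("dt", dt)
    _check_positive("tau", tau)
    if not tau_multiplies and dt > tau:
        raise ConfigurationError(
            f"dt={dt} exceeds tau={tau}; explicit Euler stepping would be unstable"
        )
    rate = tau if tau_multiplies else 1.0 / tau
    return a + dt * rate * (input_sum - a)


def step_lin(state: LINState, input_sum: float, dt: float) -> LINState:
    """Advance a :class:`LINState` by one Euler step of ``da/dt = (-a + x)/tau``."""
    return LINState(a=float(lin_update(state.a, input_sum, state.tau, dt)), tau=state.tau)


def adaptive_lin_update(a_pr, alpha, x, tau_pr: float, tau_alpha: float, dt: float):
    """One Euler step of the coupled photoreceptor/adaptation equations.

    Returns the updated ``(a_pr, alpha)`` pair.  Both updates use the value of
    the other state at the *start* of the step.
    """
    _check_positive("dt", dt)
    new_a = a_pr + dt / tau_pr * (-a_pr - alpha + x)
    new_alpha = alpha + dt / tau_alpha * (x - alpha)
    return new_a, new_alpha


def step_adaptive_lin(state: AdaptiveLINState, x: float, dt: float) -> AdaptiveLINState:
    a, alpha = adaptive_lin_update(state.a_pr, state.alpha, x, state.tau_pr, state.tau_alpha, dt)
    return AdaptiveLINState(
        a_pr=float(a), alpha=float(alpha), tau_pr=state.tau_pr, tau_alpha=state.tau_alpha
    )


def rectify(a, mode: RectifierMode):
    """Apply a rectification mode; works on scalars and arrays."""
    mode = RectifierMode(mode)
    if mode is RectifierMode.NONE:
        return a
    if mode is RectifierMode.ONSET_ONLY:
        return np.maximum(0.0, a)
    if mode is RectifierMode.OFFSET_ONLY:
        return np.maximum(0.0, np.negative(a))
    if mode is RectifierMode.FULL:
        return np.abs(a)
    raise ConfigurationError(f"unknown rectifier mode {mode!r}")  # pragma: no cover


@dataclass
class DelayLine:
    """Fixed signal delay of ``d`` ms, sample-aligned at resolution ``dt`` ms.

    The buffer holds ``round(d / dt)`` past samples (zeros initially), so the
    output at time t is exactly the input at time t - d.  ``shape`` allows one
    line to delay a whole array of parallel signals.
    """

    d: float
    dt: float
    shape: tuple = ()
    _buf: np.ndarray = field(init=False, repr=False)
    _idx: int = field(default=0, init=False, repr=False)

    def __post_init__(self) -> None:
        _check_positive("dt", self.dt)
        if self.d < 0:
            raise ConfigurationError(f"delay must be >= 0, got {self.d}")
        steps = self.d / self.dt
        n = int(round(steps))
        if abs(steps - n) > 1e-9:
            warnings.warn(
                f"delay {self.d} ms is not a multiple of dt={self.dt} ms; "
                f"rounded to {n} samples",
                stacklevel=2,
            )
        self.n_steps = n
        self._buf = np.zeros((max(n, 1),) + tuple(self.shape))

    def step(self, x):
        """Push ``x``, return the sample from ``round(d/dt)`` steps earlier."""
        if self.n_steps == 0:
            return x
        out = self._buf[self._idx].copy() if self._buf.ndim > 1 else self._buf[self._idx]
        self._buf[self._idx] = x
        self._idx = (self._idx + 1) % self.n_steps
        return out


def step_delay_line(line: DelayLine, x):
    """Functional alias for :meth:`DelayLine.step`."""
    return line.step(x)
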