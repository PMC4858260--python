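"""The Angular Velocity Detector Unit (AVDU) and retinotopic arrays of it.

An AVDU estimates angular velocity from a pair of temporal-frequency-tuned
Reichardt-Hassenstein correlators built from leaky-integrator units
(RHD-LINs).  The signal path for each pair of neighbouring input locations:

1. each location's luminance passes an adaptive photoreceptor unit and a
   rectifier (offset-only by default — dark edges become positive pulses);
2. two RHD-LIN subunits correlate the pair.  Each subunit has a *direct*
   channel (LIN, tau_b = 1 ms) and a *delay* channel — either a LIN with a
   longer time constant (dynamical delay, tau1/tau2) or an axonal DelayLine
   followed by a tau_b LIN (fixed delay, d1/d2);
3. per subunit, progressive = delayed(left) x direct(right) and regressive =
   direct(left) x delayed(right); a subtraction LIN (tau_R = 5 ms) integrates
   progressive - F * regressive, where F in [0, 1] scales down the
   anti-preferred arm to weaken spatial-frequency dependence;
4. the fast (small-delay) and slow subunit outputs are summed over the whole
   array, the summed fast response is divided by the summed slow response
   with the denominator floored at 0.01 (a tonic-rate lower bound that
   prevents division blow-up), and the ratio is smoothed by a final LIN
   (tau_S = 100 ms) to give the array output S.

Because the arms are tuned to different temporal frequencies, their ratio
tracks angular velocity — approximately log-linearly for the 5/15 ms pair —
largely independent of the pattern's spatial frequency and contrast.

The array is stepped as a struct-of-arrays (one numpy vector per stage per
location) so a few hundred detectors cost a handful of vector ops per
0.1 ms step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import ConfigurationError, DelayLine, RectifierMode, rectify

__all__ = ["AVDUParams", "ArraySums", "DetectorArray", "floored_ratio", "DT_MS"]

#: simulation resolution used throughout the model, ms
DT_MS = 0.1


@dataclass(frozen=True)
class AVDUParams:
    """Parameters shared by every AVDU in an array.

    delay_mode "dynamic" uses LINs with time constants ``tau1``/``tau2`` as
    the delay channels; "fixed" uses pure delays ``d1``/``d2`` (ms) each
    followed by a tau_b LIN.  The smaller delay always defines the *fast*
    subunit, which is the numerator of the ratio.
    """

    delay_mode: str = "dynamic"
    tau1: float = 5.0
    tau2: float = 15.0
    d1: float = 5.0
    d2: float = 15.0
    F: float = 0.25
    tau_b: float = 1.0
    tau_r: float = 5.0
    tau_s: float = 100.0
    denom_floor: float = 0.01
    rect_mode: RectifierMode = RectifierMode.OFFSET_ONLY
    tau_pr: float = 8.0
    tau_alpha: float = 15.0
    #: divide the summed responses then smooth (model default); if True the
    #: two sums are smoothed by separate tau_S LINs before the division.
    smooth_before_divide: bool = False
    #: skip the adaptive photoreceptor + rectifier stage and feed raw input
    #: to the correlator channels (used for analytic ideal-correlator checks).
    bypass_adaptive: bool = False

    def __post_init__(self) -> None:
        if self.delay_mode not in ("dynamic", "fixed"):
            raise ConfigurationError(f"unknown delay_mode {self.delay_mode!r}")
        if not 0.0 <= self.F <= 1.0:
            raise ConfigurationError(f"F must be in [0, 1], got {self.F}")
        if not self.denom_floor > 0:
            raise ConfigurationError("denom_floor must be > 0")
        if self.delay_mode == "dynamic" and self.tau1 > self.tau2:
            raise ConfigurationError("tau1 (fast arm) must not exceed tau2")
        if self.delay_mode == "fixed" and self.d1 > self.d2:
            raise ConfigurationError("d1 (fast arm) must not exceed d2")
        object.__setattr__(self, "rect_mode", RectifierMode(self.rect_mode))

    def with_(self, **kwargs) -> "AVDUParams":
        return replace(self, **kwargs)


@dataclass
class ArraySums:
    """Summed subunit outputs and the smoothed ratio S of one array."""

    sum_fast: float
    sum_slow: float
    S: float


def floored_ratio(sum_fast: float, sum_slow: float, floor: float) -> float:
    """Fast/slow ratio with the denominator bounded below by ``floor``.

    Only the denominator is floored; the numerator (and hence the ratio) may
    be negative for anti-preferred motion.
    """
    return sum_fast / max(sum_slow, floor)


class DetectorArray:
    """An array of identical AVDUs over chains of collinear input locations.

    The array spans ``n_chains`` parallel rows of ``chain_len`` locations
    each; one AVDU sits between every adjacent pair along a chain, so there
    are ``n_chains * (chain_len - 1)`` detectors.  The preferred direction is
    increasing location index within a chain.  All detectors feed a single
    summation/division/smoothing stage.
    """

    def __init__(self, n_chains: int, chain_len: int, params: AVDUParams, dt: float = DT_MS):
        if chain_len < 2:
            raise ConfigurationError("need at least two locations per chain")
        if dt <= 0:
            raise ConfigurationError("dt must be > 0")
        self.params = params
        self.dt = dt
        self.n_chains = n_chains
        self.chain_len = chain_len
        shape = (n_chains, chain_len)
        self.shape = shape
        # photoreceptor stage
        self.a_pr = np.zeros(shape)
        self.alpha = np.zeros(shape)
        # per-location channel LINs
        self.a_b = np.zeros(shape)  # direct channel
        self.a_fast = np.zeros(shape)  # delay channel, fast subunit
        self.a_slow = np.zeros(shape)  # delay channel, slow subunit
        if params.delay_mode == "fixed":
            self._line_fast = DelayLine(params.d1, dt, shape=shape)
            self._line_slow = DelayLine(params.d2, dt, shape=shape)
        else:
            self._line_fast = self._line_slow = None
        # subtraction LINs, one per AVDU per subunit
        self.r_fast = np.zeros((n_chains, chain_len - 1))
        self.r_slow = np.zeros((n_chains, chain_len - 1))
        # output stage
        self.S = 0.0
        self._s_fast = 0.0  # used only when smoothing precedes the division
        self._s_slow = 0.0

    @property
    def n_detectors(self) -> int:
        return self.n_chains * (self.chain_len - 1)

    def reset(self) -> None:
        for arr in (self.a_pr, self.alpha, self.a_b, self.a_fast, self.a_slow,
                    self.r_fast, self.r_slow):
            arr[...] = 0.0
        if self._line_fast is not None:
            self._line_fast._buf[...] = 0.0
            self._line_slow._buf[...] = 0.0
        self.S = self._s_fast = self._s_slow = 0.0

    def step(self, lum: np.ndarray) -> ArraySums:
        """Advance every unit by one ``dt`` given one luminance per location."""
        p = self.params
        dt = self.dt
        lum = np.asarray(lum, dtype=float)
        if lum.shape != self.shape:
            raise ConfigurationError(
                f"frame shape {lum.shape} does not match array layout {self.shape}"
            )
        if not np.all(np.isfinite(lum)):
            raise ConfigurationError("non-finite luminance input")

        if p.bypass_adaptive:
            x = lum
        else:
            # adaptive photoreceptor stage (both updates use start-of-step state)
            d_apr = (-self.a_pr - self.alpha + lum) * (dt / p.tau_pr)
            self.alpha += (lum - self.alpha) * (dt / p.tau_alpha)
            self.a_pr += d_apr
            x = rectify(self.a_pr, p.rect_mode)

        self.a_b += (x - self.a_b) * (dt / p.tau_b)
        if p.delay_mode == "dynamic":
            self.a_fast += (x - self.a_fast) * (dt / p.tau1)
            self.a_slow += (x - self.a_slow) * (dt / p.tau2)
        else:
            self.a_fast += (self._line_fast.step(x) - self.a_fast) * (dt / p.tau_b)
            self.a_slow += (self._line_slow.step(x) - self.a_slow) * (dt / p.tau_b)

        # correlation: progressive = delayed(left) * direct(right)
        left, right = slice(None, -1), slice(1, None)
        drive_fast = (self.a_fast[:, left] * self.a_b[:, right]
                      - p.F * self.a_b[:, left] * self.a_fast[:, right])
        drive_slow = (self.a_slow[:, left] * self.a_b[:, right]
                      - p.F * self.a_b[:, left] * self.a_slow[:, right])
        self.r_fast += (drive_fast - self.r_fast) * (dt / p.tau_r)
        self.r_slow += (drive_slow - self.r_slow) * (dt / p.tau_r)

        sum_fast = float(self.r_fast.sum())
        sum_slow = float(self.r_slow.sum())
        if p.smooth_before_divide:
            self._s_fast += (sum_fast - self._s_fast) * (dt / p.tau_s)
            self._s_slow += (sum_slow - self._s_slow) * (dt / p.tau_s)
            self.S = floored_ratio(self._s_fast, self._s_slow, p.denom_floor)
        else:
            r = floored_ratio(sum_fast, sum_slow, p.denom_floor)
            self.S += (r - self.S) * (dt / p.tau_s)
        if not np.isfinite(self.S):
            raise ConfigurationError("detector output diverged (non-finite S)")
        return ArraySums(sum_fast=sum_fast, sum_slow=sum_slow, S=self.S)

    def subunit_probe(self) -> tuple[float, float]:
        """Per-detector mean fast and slow RHD-LIN outputs, before the division.

        This is the population optomotor-style signal of each subunit; the
        temporal-frequency tuning of these probes is what links the model to
        classical optomotor neurons.
        """
        return float(self.r_fast.mean()), float(self.r_slow.mean())
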