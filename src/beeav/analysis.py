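"""Open-loop measurement protocols and response-curve fitting.

Every response value follows the same protocol: run the test system on a
drifting grating for 2 s and average the output over the final 1 s, by which
time the smoothed ratio S has reached steady state.  Sweeps repeat this with
a fresh detector state per grid point, over angular velocity (deg/s) or
temporal frequency (Hz).

Response-vs-AV curves are summarised by ordinary least-squares fits of three
forms — linear ``y = a + b*x``, logarithmic ``y = a + b*ln(x)`` and
exponential (``ln y`` regressed on x over the positive responses) — ranked
by adjusted R².  The signature of angular-velocity tuning is that the
logarithmic form wins over the working range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, RectifierMode
from .detector import DT_MS, AVDUParams
from .systems import TestSystem, build_test_system
from .world import Grating, TestArrayGeometry

__all__ = [
    "ResponseCurve", "FitResult", "measure_response", "measure_subunits",
    "sweep_av", "sweep_tf_subunits", "fit_forms", "rectification_comparison",
    "invariance_table", "default_av_grid", "default_tf_grid",
]

#: default measurement protocol, seconds
DURATION_S = 2.0
WINDOW_S = 1.0


def default_av_grid(lo: float = 10.0, hi: float = 1000.0,
                    points_per_decade: int = 10) -> np.ndarray:
    """Log-spaced angular-velocity grid, deg/s."""
    n = int(round(points_per_decade * math.log10(hi / lo))) + 1
    return np.logspace(math.log10(lo), math.log10(hi), n)


def default_tf_grid(lo: float = 0.25, hi: float = 100.0,
                    points_per_decade: int = 10) -> np.ndarray:
    """Temporal-frequency grid anchored so that 10**(k/10) Hz points (and in
    particular 10 Hz exactly) lie on the grid."""
    k_lo = math.ceil(points_per_decade * math.log10(lo) - 1e-9)
    k_hi = math.floor(points_per_decade * math.log10(hi) + 1e-9)
    return 10.0 ** (np.arange(k_lo, k_hi + 1) / points_per_decade)


@dataclass
class ResponseCurve:
    """Mean detector response against an independent variable grid."""

    kind: str  # "angular_velocity" (deg/s) or "temporal_frequency" (Hz)
    grid: np.ndarray
    response: np.ndarray
    stimulus: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ConfigurationError("grid must be strictly increasing")
        if self.response.shape != self.grid.shape:
            raise ConfigurationError("one response per grid point required")

    @property
    def peak(self) -> float:
        """Grid value at which the response is maximal."""
        return float(self.grid[int(np.argmax(self.response))])


def _run_protocol(system: TestSystem, g: Grating, duration: float,
                  window: float, probe_subunits: bool) -> tuple[float, ...]:
    dt_s = system.dt / 1000.0
    n_steps = int(round(duration / dt_s))
    n_window = int(round(window / dt_s))
    acc_s = acc_f = acc_sl = 0.0
    start = n_steps - n_window
    for i in range(n_steps):
        sums = system.step(g, i * dt_s)
        if i >= start:
            acc_s += sums.S
            if probe_subunits:
                f, s = system.array.subunit_probe()
                acc_f += f
                acc_sl += s
    if not np.isfinite(acc_s):
        raise ConfigurationError(f"non-finite response for stimulus {g!r}")
    if probe_subunits:
        return acc_s / n_window, acc_f / n_window, acc_sl / n_window
    return (acc_s / n_window,)


def measure_response(params: AVDUParams, g: Grating, duration: float = DURATION_S,
                     window: float = WINDOW_S, dt: float = DT_MS,
                     geom: TestArrayGeometry | None = None) -> float:
    """Mean smoothed ratio S over the final ``window`` s of a ``duration`` s run."""
    system = build_test_system(params, geom, dt)
    return _run_protocol(system, g, duration, window, False)[0]


def measure_subunits(params: AVDUParams, g: Grating, duration: float = DURATION_S,
                     window: float = WINDOW_S, dt: float = DT_MS,
                     geom: TestArrayGeometry | None = None) -> tuple[float, float]:
    """Time-mean per-detector (fast, slow) RHD-LIN outputs before the division."""
    system = build_test_system(params, geom, dt)
    return _run_protocol(system, g, duration, window, True)[1:]


def sweep_av(params: AVDUParams, wavelength: float = 38.0, contrast: float = 1.0,
             grid: np.ndarray | None = None, waveform: str = "square",
             duration: float = DURATION_S, window: float = WINDOW_S,
             dt: float = DT_MS) -> ResponseCurve:
    """Mean S across an angular-velocity grid; fresh detector state per point."""
    grid = default_av_grid() if grid is None else np.asarray(grid, dtype=float)
    resp = [measure_response(
        params, Grating(waveform=waveform, wavelength=wavelength,
                        angular_velocity=av, contrast=contrast),
        duration, window, dt) for av in grid]
    return ResponseCurve("angular_velocity", grid, np.array(resp),
                         stimulus=f"{waveform} {wavelength:g} deg, contrast {contrast:g}")


def sweep_tf_subunits(params: AVDUParams, wavelengths=(11.0, 19.0, 38.0),
                      tf_grid: np.ndarray | None = None, waveform: str = "square",
                      contrast: float = 1.0, duration: float = DURATION_S,
                      window: float = WINDOW_S, dt: float = DT_MS,
                      ) -> dict[float, tuple[ResponseCurve, ResponseCurve]]:
    """Pre-division subunit tuning curves vs temporal frequency per wavelength.

    The stimulus angular velocity for each grid point is tf * wavelength, so
    the same temporal frequencies are compared across spatial wavelengths.
    Returns {wavelength: (fast_curve, slow_curve)}.
    """
    tf_grid = default_tf_grid() if tf_grid is None else np.asarray(tf_grid, dtype=float)
    out: dict[float, tuple[ResponseCurve, ResponseCurve]] = {}
    for wl in wavelengths:
        fast, slow = [], []
        for tf in tf_grid:
            f, s = measure_subunits(
                params, Grating(waveform=waveform, wavelength=wl,
                                angular_velocity=tf * wl, contrast=contrast),
                duration, window, dt)
            fast.append(f)
            slow.append(s)
        label = f"{waveform} {wl:g} deg"
        out[wl] = (ResponseCurve("temporal_frequency", tf_grid, np.array(fast), label),
                   ResponseCurve("temporal_frequency", tf_grid, np.array(slow), label))
    return out


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A two-parameter OLS fit of a response curve."""

    form: str  # linear | logarithmic | exponential
    intercept: float
    slope: float
    adjusted_r2: float
    available: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.intercept + self.slope * x
        if self.form == "logarithmic":
            return self.intercept + self.slope * np.log(x)
        return np.exp(self.intercept + self.slope * x)


def _ols(design_x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit y = a + b*design_x; returns (a, b, adjusted R^2) with p = 1 predictor."""
    n = len(y)
    X = np.column_stack([np.ones(n), design_x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(coef[0]), float(coef[1]), adj


def fit_forms(curve: ResponseCurve) -> dict[str, FitResult]:
    """Fit linear, logarithmic and exponential forms; key "best" names the
    form with the highest adjusted R² among the available fits."""
    x, y = curve.grid, curve.response
    if len(x) < 4:
        raise ConfigurationError("need at least 4 points to fit")
    results: dict[str, FitResult] = {}
    a, b, adj = _ols(x, y)
    results["linear"] = FitResult("linear", a, b, adj)
    a, b, adj = _ols(np.log(x), y)
    results["logarithmic"] = FitResult("logarithmic", a, b, adj)
    pos = y > 0
    if pos.sum() >= 4:
        a, b, adj = _ols(x[pos], np.log(y[pos]))
        results["exponential"] = FitResult("exponential", a, b, adj)
    else:
        results["exponential"] = FitResult("exponential", math.nan, math.nan,
                                           -math.inf, available=False)
    best = max((r for r in results.values() if r.available),
               key=lambda r: r.adjusted_r2)
    results["best"] = best
    return results


def rectification_comparison(params: AVDUParams, wavelength: float = 38.0,
                             grid: np.ndarray | None = None,
                             **kwargs) -> dict[str, ResponseCurve]:
    """AV sweeps of the same detector under all four rectification modes."""
    return {mode.value: sweep_av(params.with_(rect_mode=mode), wavelength,
                                 grid=grid, **kwargs)
            for mode in RectifierMode}


def invariance_table(params: AVDUParams,
                     avs=(50.0, 100.0, 200.0, 500.0),
                     contrasts=(0.25, 0.5, 1.0),
                     wavelengths=(11.0, 19.0, 38.0),
                     base_wavelength: float = 19.0,
                     base_contrast: float = 1.0,
                     **kwargs) -> dict[str, dict]:
    """Coefficient of variation of mean S across contrasts and wavelengths.

    Contrast is varied at the base wavelength and wavelength at the base
    contrast; the CoV at each AV summarises how invariant the estimate is to
    the stimulus at that speed.
    """
    def cov(values: list[float]) -> float:
        arr = np.asarray(values)
        return float(arr.std(ddof=0) / abs(arr.mean()))

    out: dict[str, dict] = {"contrast": {}, "wavelength": {}}
    for av in avs:
        vals = [measure_response(params, Grating(
            wavelength=base_wavelength, angular_velocity=av, contrast=c), **kwargs)
            for c in contrasts]
        out["contrast"][av] = {"responses": vals, "cov": cov(vals)}
        vals = [measure_response(params, Grating(
            wavelength=wl, angular_velocity=av, contrast=base_contrast), **kwargs)
            for wl in wavelengths]
        out["wavelength"][av] = {"responses": vals, "cov": cov(vals)}
    return out
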