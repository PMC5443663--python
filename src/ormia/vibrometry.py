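"""Laser-vibrometry style analysis of tympanal vibration traces.

The analysis chain: smooth a vibration trace with a sliding RMS window,
measure the *effective amplitude* — the dB amount by which the signal-driven
response exceeds the masker-driven noise floor — separately for each ear,
difference the two ears to obtain the effective interaural vibration
amplitude difference (IVAD, dB), fit an antisymmetric sigmoid of IVAD versus
source azimuth, and invert the fitted curve to translate a measured IVAD into
a predicted incident sound direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "EffectiveAmplitude",
    "IvadMeasurement",
    "FittedSigmoid",
    "sliding_rms",
    "pulse_window_schedule",
    "effective_amplitude",
    "compute_ivad",
    "fit_sigmoid",
    "predict_direction",
]


def sliding_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding RMS; edges shrink to the valid part of the window.

    output[i] = RMS of x over the window centred at i.  Length is preserved
    and a constant input maps to its absolute value everywhere.
    """
    x = np.asarray(x, dtype=float)
    if window < 2:
        raise ValueError("window must be at least 2 samples")
    if window > len(x):
        raise ValueError("window exceeds trace length")
    sq = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(len(x))
    half_lo = (window - 1) // 2
    half_hi = window // 2
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, len(x))
    return np.sqrt((sq[hi] - sq[lo]) / (hi - lo))


def window_rms(x: np.ndarray, start: int, stop: int) -> float:
    """Plain RMS of x[start:stop]."""
    seg = np.asarray(x[start:stop], dtype=float)
    if seg.size == 0:
        raise ValueError("empty analysis window")
    return float(np.sqrt(np.mean(seg * seg)))


@dataclass
class EffectiveAmplitude:
    """Per-ear signal-above-noise-floor measure, in dB.

    ``per_iteration_db`` holds one value per signal repetition (pulse or
    pulse-group window); ``value_db`` is their arithmetic mean.
    """

    ear: str
    per_iteration_db: list[float]
    value_db: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.per_iteration_db) == 0:
            raise ValueError("need at least one iteration")
        if not np.all(np.isfinite(self.per_iteration_db)):
            raise ValueError("non-finite effective amplitude")
        self.value_db = float(np.mean(self.per_iteration_db))


@dataclass
class IvadMeasurement:
    value_db: float
    snr_db: Optional[float] = None


def pulse_window_schedule(signal_onset_s: float,
                          n_iterations: int,
                          fs_hz: float,
                          period_s: float = 0.4,
                          window_s: float = 0.030,
                          masker_delay_s: float = 0.2) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Default analysis-window schedule for repeated signal presentations.

    Signal windows: ``window_s`` segments at each signal-pulse onset; masker
    (noise-floor) windows: equal segments in the middle of the inter-pulse
    interval, ``masker_delay_s`` after each signal onset, for presentations
    repeated every ``period_s``.
    """
    sig, mask = [], []
    w = int(round(window_s * fs_hz))
    for k in range(n_iterations):
        s0 = int(round((signal_onset_s + k * period_s) * fs_hz))
        m0 = int(round((signal_onset_s + k * period_s + masker_delay_s) * fs_hz))
        sig.append((s0, s0 + w))
        mask.append((m0, m0 + w))
    return sig, mask


def effective_amplitude(trace: np.ndarray,
                        signal_windows: Sequence[tuple[int, int]],
                        masker_windows: Sequence[tuple[int, int]],
                        ear: str = "unspecified",
                        smooth_window: Optional[int] = None) -> EffectiveAmplitude:
    """Effective response amplitude: signal-epoch RMS over masker-epoch RMS, in dB.

    Each iteration pairs one signal window with one masker window;
    value_db[k] = 20 log10(RMS_signal[k] / RMS_masker[k]).  With
    ``smooth_window`` the RMS is read as the peak of the sliding-RMS envelope
    inside each window, mirroring smoothed-trace measurement.
    """
    if len(signal_windows) == 0 or len(masker_windows) == 0:
        raise ValueError("need at least one signal and one masker window")
    if len(signal_windows) != len(masker_windows):
        raise ValueError("signal and masker windows must pair one-to-one")
    x = np.asarray(trace, dtype=float)
    if smooth_window is not None:
        env = sliding_rms(x, smooth_window)
        measure = lambda a, b: float(np.max(env[a:b]))
    else:
        measure = lambda a, b: window_rms(x, a, b)
    vals = []
    for (s0, s1), (m0, m1) in zip(signal_windows, masker_windows):
        rs = measure(s0, s1)
        rm = measure(m0, m1)
        if rm <= 0:
            raise ValueError("zero-RMS masker window: dB difference undefined")
        vals.append(20.0 * np.log10(rs / rm))
    return EffectiveAmplitude(ear=ear, per_iteration_db=vals)


def compute_ivad(contra: EffectiveAmplitude, ipsi: EffectiveAmplitude,
                 snr_db: Optional[float] = None) -> IvadMeasurement:
    """Effective IVAD = contralateral minus ipsilateral effective amplitude (dB).

    Positive values mean the masker-contralateral ear dominates, i.e. the
    perceived signal direction is biased away from the masker.
    """
    return IvadMeasurement(value_db=contra.value_db - ipsi.value_db, snr_db=snr_db)


# ---------------------------------------------------------------------------
# Sigmoid fitting and inversion
# ---------------------------------------------------------------------------

def _logistic(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    y0, amp, x0, s = params
    return y0 + amp / (1.0 + np.exp(-(x - x0) / s))


@dataclass
class FittedSigmoid:
    """4-parameter logistic y = y0 + amp / (1 + exp(-(x - x0)/s))."""

    y0: float
    amp: float
    x0: float
    slope: float
    rss: float
    converged: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.y0, self.amp, self.x0, self.slope])

    def __call__(self, x) -> np.ndarray:
        return _logistic(self.params, np.asarray(x, dtype=float))

    @property
    def increasing(self) -> bool:
        return self.amp / self.slope > 0


def fit_sigmoid(xs: Sequence[float], ys: Sequence[float],
                n_starts: int = 5, seed: int = 0) -> FittedSigmoid:
    """Least-squares logistic fit by derivative-free simplex (Nelder-Mead).

    Multi-start: ``n_starts`` simplex runs from perturbed data-driven initial
    guesses; the lowest-RSS solution wins.  ``converged`` reflects the simplex
    tolerance (1e-8 on RSS change).  Degenerate data (constant ys) yield
    ``converged=False`` rather than an exception.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit a 4-parameter sigmoid")
    if np.ptp(y) == 0:
        return FittedSigmoid(y0=float(y[0]), amp=0.0, x0=float(np.mean(x)),
                             slope=1.0, rss=0.0, converged=False)

    def rss_fn(p: np.ndarray) -> float:
        if p[3] == 0:
            return np.inf
        with np.errstate(over="ignore"):
            r = y - _logistic(p, x)
        return float(np.dot(r, r))

    span_x = np.ptp(x) or 1.0
    # data-driven starts for both orientations (rising and falling)
    base_inc = np.array([float(np.min(y)), float(np.ptp(y)),
                         float(np.median(x)), span_x / 4.0])
    base_dec = np.array([float(np.max(y)), -float(np.ptp(y)),
                         float(np.median(x)), span_x / 4.0])
    increasing_guess = np.corrcoef(x, y)[0, 1] >= 0
    bases = ([base_inc, base_dec] if increasing_guess else [base_dec, base_inc])
    # additive perturbation scales (a multiplicative jitter would freeze any
    # coordinate whose starting value is zero, e.g. a centred inflection)
    scale = np.array([np.ptp(y), np.ptp(y), span_x / 2.0, span_x / 4.0])
    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(n_starts, 2)):
        p0 = bases[k % 2].copy()
        if k > 1:
            p0 = p0 + 0.5 * scale * rng.standard_normal(4)
            if p0[3] == 0:
                p0[3] = span_x / 4.0
        res = minimize(rss_fn, p0, method="Nelder-Mead",
                       options={"fatol": 1e-8, "xatol": 1e-8,
                                "maxiter": 4000, "maxfev": 8000})
        # one restart from the incumbent re-inflates a collapsed simplex
        res2 = minimize(rss_fn, res.x, method="Nelder-Mead",
                        options={"fatol": 1e-8, "xatol": 1e-8,
                                 "maxiter": 4000, "maxfev": 8000})
        if res2.fun < res.fun:
            res = res2
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    y0, amp, x0, s = best.x
    if s < 0:  # canonical orientation: positive slope parameter
        y0, amp, x0, s = y0 + amp, -amp, x0, -s
    return FittedSigmoid(y0=float(y0), amp=float(amp), x0=float(x0),
                         slope=float(s), rss=float(best.fun),
                         converged=bool(best.success))


def predict_direction(ivad: IvadMeasurement | float, curve: FittedSigmoid,
                      x_lo: float = -180.0, x_hi: float = 180.0,
                      tol: float = 1e-9) -> float:
    """Invert the fitted IVAD-vs-azimuth curve at a measured IVAD (bisection).

    Values beyond the curve's range over [x_lo, x_hi] clamp to the endpoints
    with a warning.  Raises if the fit is not monotone over the range.
    """
    y = ivad.value_db if isinstance(ivad, IvadMeasurement) else float(ivad)
    ylo, yhi = float(curve(x_lo)), float(curve(x_hi))
    if ylo == yhi or curve.amp == 0:
        raise ValueError("fitted curve is not monotone; cannot invert")
    sign = 1.0 if yhi > ylo else -1.0
    grid = curve(np.linspace(x_lo, x_hi, 257))
    if np.any(sign * np.diff(grid) < -1e-12):
        raise ValueError("fitted curve is not monotone; cannot invert")
    lo_val, hi_val = min(ylo, yhi), max(ylo, yhi)
    if y <= lo_val or y >= hi_val:
        if y < lo_val or y > hi_val:
            warnings.warn("IVAD outside the fitted curve's range; clamping",
                          RuntimeWarning, stacklevel=2)
        if sign > 0:
            return x_lo if y <= lo_val else x_hi
        return x_hi if y <= lo_val else x_lo
    a, b = x_lo, x_hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if sign * (float(curve(mid)) - y) < 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
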